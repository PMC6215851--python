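"""Synthetic multi-sample OTU datasets with known ground truth.

Emulates the structure of a two-group human gut study — tens of fecal
samples per host group, per-sample read depths in the thousands, a few
hundred taxa — under three generative regimes:

``etienne_neutral``
    Every sample is a dispersal-limited neutral draw: each read descends
    from a new immigrant ancestor with probability ``I/(I+j-1)`` (the
    immigrant's taxon drawn from a shared metacommunity) or copies an
    earlier read.  The positive control for the community-level exact test.

``sloan_neutral``
    Per sample and taxon, a relative abundance is drawn from the stationary
    beta law ``Beta(J m p_i, J m (1-p_i))``, compositions renormalized, and
    reads sampled multinomially.  The positive control for the species-level
    Sloan test.

``niche``
    Deterministic selection: per-sample taxon weights are the metacommunity
    tilted by ``exp(selection_strength * z_i * e_s)`` with fixed per-taxon
    responses ``z_i`` and a per-sample environment ``e_s``, plus an optional
    group-specific multiplicative shift on a designated taxon subset (a
    coarse analogue of a between-group composition change such as a
    Firmicutes/Bacteroidetes ratio shift).  ``selection_strength = 0`` with
    no group effect reduces to plain multinomial (neutral) sampling.  The
    negative control for both tests.

All generators are pure functions of (design, seed) and return a validated
:class:`~neutralassembly.otu_io.OTUTable`, a group map, and a JSON-ready
truth record for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .etienne import I_from_m
from .otu_io import GroupMap, OTUTable

__all__ = [
    "SyntheticDesign",
    "logseries_metacommunity",
    "generate_neutral_dataset",
    "generate_niche_dataset",
    "generate_dataset",
]

_GROUP_LABELS = ["lean", "obese", "overweight"]

MODES = ("etienne_neutral", "sloan_neutral", "niche")


@dataclass
class SyntheticDesign:
    """Ground-truth parameters of a generated multi-sample dataset.

    Defaults are the desk-scale study emulation: 2 host groups x 30 samples,
    J = 1000 reads per sample with +/-50% uniform depth variation, and a
    log-series metacommunity with theta = 30 (a few hundred taxa).
    """

    mode: str = "etienne_neutral"
    n_groups: int = 2
    samples_per_group: int = 30
    J: int = 1000
    depth_variation: bool = True  # per-sample depth uniform on [J/2, 3J/2]
    theta: float = 30.0
    m: float = 0.15
    J_meta: int = 100_000
    selection_strength: float = 0.0
    group_effect_taxa: int = 0
    group_effect_multiplier: float = 1.0
    seed: int = 0
    metacommunity: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_groups < 1 or self.samples_per_group < 1:
            raise ValueError("need at least one group and one sample per group")
        if self.J < 1 or self.theta <= 0 or not 0 < self.m < 1:
            raise ValueError("invalid J, theta or m")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")
        if self.metacommunity is not None:
            mc = np.asarray(self.metacommunity, dtype=float)
            if np.any(mc < 0) or abs(mc.sum() - 1.0) > 1e-8:
                raise ValueError("metacommunity must be non-negative and sum to 1")
            self.metacommunity = mc

    @property
    def group_labels(self) -> list[str]:
        labels = list(_GROUP_LABELS)
        labels += [f"group{i + 1}" for i in range(len(labels), self.n_groups)]
        return labels[: self.n_groups]


def logseries_metacommunity(
    theta: float, J_meta: int = 100_000, seed=None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Relative abundances of a neutral (Ewens / log-series) metacommunity.

    Runs the Hoppe-urn construction over ``J_meta`` individuals: individual
    ``k`` founds a new species with probability ``theta / (theta + k - 1)``,
    otherwise copies an earlier individual.  Returns abundances normalized
    to sum 1, sorted descending.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if J_meta < 1:
        raise ValueError("J_meta must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    J_meta = int(J_meta)
    u_new = rng.random(J_meta)
    u_pick = rng.random(J_meta)
    species = np.empty(J_meta, dtype=np.int64)
    n_sp = 0
    for k in range(J_meta):
        if u_new[k] * (theta + k) < theta:
            species[k] = n_sp
            n_sp += 1
        else:
            species[k] = species[int(u_pick[k] * k)]
    counts = np.bincount(species, minlength=n_sp)
    rel = np.sort(counts)[::-1] / J_meta
    return rel


def _sample_ids_and_groups(design: SyntheticDesign) -> tuple[list[str], GroupMap]:
    ids, mapping = [], {}
    for g, label in enumerate(design.group_labels):
        for s in range(design.samples_per_group):
            sid = f"{label}_{s + 1:03d}"
            ids.append(sid)
            mapping[sid] = label
    return ids, GroupMap(mapping)


def _depths(design: SyntheticDesign, rng: np.random.Generator) -> np.ndarray:
    n = design.n_groups * design.samples_per_group
    if not design.depth_variation:
        return np.full(n, design.J, dtype=np.int64)
    low = max(1, design.J // 2)
    high = design.J + design.J // 2
    return rng.integers(low, high + 1, size=n)


def _etienne_sample_from_pool(
    p: np.ndarray, m: float, J_s: int, rng: np.random.Generator
) -> np.ndarray:
    """One dispersal-limited draw of ``J_s`` reads from metacommunity ``p``."""
    I = I_from_m(m, J_s) if J_s > 1 else 1.0
    immigrant_taxon = rng.choice(p.size, size=J_s, p=p)
    u_new = rng.random(J_s)
    u_pick = rng.random(J_s)
    taxon = np.empty(J_s, dtype=np.int64)
    for j in range(J_s):
        if u_new[j] * (I + j) < I:
            taxon[j] = immigrant_taxon[j]
        else:
            taxon[j] = taxon[int(u_pick[j] * j)]
    return np.bincount(taxon, minlength=p.size)


def _base(design: SyntheticDesign):
    rng = np.random.default_rng(design.seed)
    p = (
        design.metacommunity
        if design.metacommunity is not None
        else logseries_metacommunity(design.theta, design.J_meta, rng=rng)
    )
    sample_ids, groups = _sample_ids_and_groups(design)
    depths = _depths(design, rng)
    taxon_ids = [f"otu_{i + 1:04d}" for i in range(p.size)]
    return rng, p, sample_ids, groups, depths, taxon_ids


def generate_neutral_dataset(design: SyntheticDesign):
    """Generate a neutral dataset (``etienne_neutral`` or ``sloan_neutral``).

    Returns ``(OTUTable, GroupMap, truth)`` where ``truth`` records the
    generative parameters (JSON-serializable).
    """
    if design.mode not in ("etienne_neutral", "sloan_neutral"):
        raise ValueError("generate_neutral_dataset requires a neutral mode")
    rng, p, sample_ids, groups, depths, taxon_ids = _base(design)
    counts = np.zeros((len(sample_ids), p.size), dtype=np.int64)
    if design.mode == "etienne_neutral":
        for s, J_s in enumerate(depths):
            counts[s] = _etienne_sample_from_pool(p, design.m, int(J_s), rng)
    else:
        alpha = design.J * design.m * p
        beta = design.J * design.m * (1.0 - p)
        for s, J_s in enumerate(depths):
            rel = rng.beta(alpha, beta)
            total = rel.sum()
            if total <= 0:  # pragma: no cover - essentially impossible
                rel = p
                total = 1.0
            counts[s] = rng.multinomial(int(J_s), rel / total)
    table = OTUTable(counts, sample_ids, taxon_ids)
    truth = {
        "mode": design.mode,
        "theta": design.theta,
        "m": design.m,
        "J": design.J,
        "N_T": design.J,
        "seed": design.seed,
        "depths": depths.tolist(),
        "metacommunity": p.tolist(),
        "group_labels": design.group_labels,
        "samples_per_group": design.samples_per_group,
    }
    return table, groups, truth


def generate_niche_dataset(design: SyntheticDesign):
    """Generate a niche-structured (deterministically filtered) dataset.

    Per-taxon responses ``z_i ~ N(0,1)`` are fixed across the dataset; each
    sample has an environment ``e_s ~ N(0,1)`` and taxon weights
    ``p_i * exp(selection_strength * z_i * e_s)``.  When a group effect is
    configured, a random taxon subset is multiplied by
    ``group_effect_multiplier`` in every group after the first.
    """
    if design.mode != "niche":
        raise ValueError("generate_niche_dataset requires mode='niche'")
    rng, p, sample_ids, groups, depths, taxon_ids = _base(design)
    z = rng.standard_normal(p.size)
    env = rng.standard_normal(len(sample_ids))
    effect_taxa = (
        rng.choice(p.size, size=min(design.group_effect_taxa, p.size), replace=False)
        if design.group_effect_taxa > 0
        else np.empty(0, dtype=np.int64)
    )
    counts = np.zeros((len(sample_ids), p.size), dtype=np.int64)
    first_group = design.group_labels[0]
    for s, sid in enumerate(sample_ids):
        w = p * np.exp(design.selection_strength * z * env[s])
        if effect_taxa.size and groups[sid] != first_group:
            w = w.copy()
            w[effect_taxa] *= design.group_effect_multiplier
        counts[s] = rng.multinomial(int(depths[s]), w / w.sum())
    table = OTUTable(counts, sample_ids, taxon_ids)
    truth = {
        "mode": "niche",
        "theta": design.theta,
        "m": design.m,
        "J": design.J,
        "seed": design.seed,
        "depths": depths.tolist(),
        "metacommunity": p.tolist(),
        "selection_strength": design.selection_strength,
        "z": z.tolist(),
        "environment": env.tolist(),
        "group_effect_taxa": [taxon_ids[i] for i in effect_taxa],
        "group_effect_multiplier": design.group_effect_multiplier,
        "group_labels": design.group_labels,
        "samples_per_group": design.samples_per_group,
    }
    return table, groups, truth


def generate_dataset(design: SyntheticDesign):
    """Dispatch on ``design.mode``."""
    if design.mode == "niche":
        return generate_niche_dataset(design)
    return generate_neutral_dataset(design)
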