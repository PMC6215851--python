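"""End-to-end cross-scale analysis: community-level exact tests on every
sample plus species-level Sloan designs, with config, seeding, logging and
TSV reports.

The community-scale report has one row per sample (ID, J, S, theta, m,
logL0, logL1, q, p, plus a pass flag) and a summary
count of communities judged neutral at the configured alpha.  The
species-scale report has one row per source -> destination design with
means and SDs over balanced resampling repeats, plus pairwise t-tests on
per-repeat neutral percentages.  All outputs are deterministic functions of
(config, seed): reports carry a provenance header (package version, seed,
config hash) and no timestamps, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .etienne import I_from_m, exact_neutrality_test, simulate_etienne_sample
from .otu_io import (
    TABLE1_COLUMNS,
    TABLE2_COLUMNS,
    CommunitySAD,
    GroupMap,
    OTUTable,
    read_group_map,
    read_otu_table,
    sample_to_sad,
)
from .sloan import (
    compare_neutral_percentages,
    fit_sloan_from_table,
    resampled_sloan_analysis,
)

__all__ = [
    "CommunityScaleConfig",
    "SpeciesScaleConfig",
    "AnalysisConfig",
    "run_community_scale",
    "run_species_scale",
    "export_rank_abundance",
    "run",
]

logger = logging.getLogger("neutralassembly")


@dataclass
class CommunityScaleConfig:
    enabled: bool = True
    n_sim: int = 100
    alpha: float = 0.05
    max_samples: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SpeciesScaleConfig:
    enabled: bool = True
    designs: list = field(
        default_factory=lambda: [("lean", "lean"), ("obese", "obese"), ("lean", "obese")]
    )
    n_per_group: int = 50
    n_repeats: int = 30
    detection_threshold: float | None = None
    r2_pass: float = 0.5
    interval: str = "wilson"

    def __post_init__(self):
        self.designs = [tuple(d) for d in self.designs]


@dataclass
class AnalysisConfig:
    """Full configuration of one pipeline run.

    Every threshold of the analysis (alpha = 0.05, R² pass = 0.5, 50 samples
    per group, 30 repeats, 100 simulated communities) is an explicit,
    config-visible field.
    """

    otu_path: str
    groups_path: str | None = None
    out_dir: str = "results"
    seed: int = 0
    samples_as_rows: bool = True
    community_scale: CommunityScaleConfig = field(default_factory=CommunityScaleConfig)
    species_scale: SpeciesScaleConfig = field(default_factory=SpeciesScaleConfig)
    rank_abundance_sims: int = 10

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        cs = CommunityScaleConfig(**raw.pop("community_scale", {}))
        ss = SpeciesScaleConfig(**raw.pop("species_scale", {}))
        return cls(community_scale=cs, species_scale=ss, **raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def sha256(self) -> str:
        """Hash of the analysis-defining fields (output location excluded,
        so re-running the same analysis elsewhere yields identical reports)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance_lines(config: AnalysisConfig) -> list[str]:
    return [
        f"# neutralassembly {__version__}",
        f"# seed={config.seed}",
        f"# config_sha256={config.sha256()}",
    ]


def _write_report(df: pd.DataFrame, path: Path, config: AnalysisConfig, extra: list[str] = ()):
    with open(path, "w") as fh:
        for line in _provenance_lines(config):
            fh.write(line + "\n")
        for line in extra:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run_community_scale(
    table: OTUTable,
    n_sim: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    max_samples: int | None = None,
) -> pd.DataFrame:
    """Exact neutrality test on every sample of the table.

    Samples are independent; sample ``i`` uses seed ``seed + i``, so any
    subset or execution order reproduces identical per-sample rows.
    Per-sample failures are recorded in the ``error`` column, not raised.
    """
    sample_ids = table.sample_ids[:max_samples] if max_samples else table.sample_ids
    rows = []
    for i, sid in enumerate(sample_ids):
        row = {c: np.nan for c in TABLE1_COLUMNS}
        row["ID"] = sid
        row["neutral"] = False
        row["error"] = ""
        try:
            sad = sample_to_sad(table, sid)
            res = exact_neutrality_test(sad, n_sim=n_sim, seed=seed + i)
            row.update(
                J=sad.J,
                S=sad.S,
                theta=res.fit.params.theta,
                m=res.fit.params.m,
                logL0=res.log_l0,
                logL1=res.log_l1,
                q=res.q,
                p=res.p,
                neutral=res.passes(alpha),
            )
        except Exception as exc:  # per-sample failures are not fatal
            row["error"] = str(exc)
            logger.warning("sample %s failed: %s", sid, exc)
        logger.info("community-scale %d/%d: %s", i + 1, len(sample_ids), sid)
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE1_COLUMNS + ["neutral", "error"])


def run_species_scale(
    table: OTUTable,
    groups: GroupMap,
    designs=(("lean", "lean"), ("obese", "obese"), ("lean", "obese")),
    n_per_group: int = 50,
    n_repeats: int = 30,
    detection_threshold: float | None = None,
    r2_pass: float = 0.5,
    interval: str = "wilson",
    seed: int = 0,
):
    """Sloan analysis for each source -> destination design.

    Returns ``(summary, ttests, summaries)``: one summary row per design
    (means and SDs over repeats, with an ``R2_pass`` flag at the configured
    threshold), pairwise t-tests on per-repeat neutral percentages, and the
    underlying per-design resampling objects.
    """
    summaries = []
    for k, (src, dst) in enumerate(designs):
        summaries.append(
            resampled_sloan_analysis(
                table,
                groups,
                src,
                dst,
                n_per_group=n_per_group,
                n_repeats=n_repeats,
                seed=seed + 1000 * k,
                detection_threshold=detection_threshold,
                interval=interval,
            )
        )
    rows = []
    for s in summaries:
        mean, sd = s.mean, s.sd
        rows.append(
            {
                "source": s.source,
                "destination": s.destination,
                "N": mean["N"],
                "m": mean["m"],
                "R2": mean["R2"],
                "total": mean["total"],
                "pct_neutral": mean["pct_neutral"],
                "pct_non_neutral": mean["pct_non_neutral"],
                "N_sd": sd["N"],
                "m_sd": sd["m"],
                "R2_sd": sd["R2"],
                "total_sd": sd["total"],
                "pct_neutral_sd": sd["pct_neutral"],
                "pct_non_neutral_sd": sd["pct_non_neutral"],
                "R2_pass": bool(mean["R2"] >= r2_pass),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=TABLE2_COLUMNS
        + ["N_sd", "m_sd", "R2_sd", "total_sd", "pct_neutral_sd", "pct_non_neutral_sd", "R2_pass"],
    )
    trows = []
    for a, b in itertools.combinations(range(len(summaries)), 2):
        t, p = compare_neutral_percentages(summaries[a], summaries[b])
        trows.append(
            {
                "design_a": f"{summaries[a].source}->{summaries[a].destination}",
                "design_b": f"{summaries[b].source}->{summaries[b].destination}",
                "t": t,
                "p": p,
            }
        )
    ttests = pd.DataFrame(trows, columns=["design_a", "design_b", "t", "p"])
    return summary, ttests, summaries


def export_rank_abundance(
    sad: CommunitySAD, theta: float, I: float, n_sim: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Long-format rank-abundance data: the observed community plus
    ``n_sim`` neutral simulations at (theta, I, J), log-scale abundances."""
    frames = [
        pd.DataFrame(
            {
                "curve": "observed",
                "rank": np.arange(1, sad.S + 1),
                "log_abundance": np.log(sad.abundances.astype(float)),
            }
        )
    ]
    children = np.random.SeedSequence(seed).spawn(n_sim)
    for k in range(n_sim):
        sim = simulate_etienne_sample(theta, I, sad.J, rng=np.random.default_rng(children[k]))
        frames.append(
            pd.DataFrame(
                {
                    "curve": f"sim_{k + 1}",
                    "rank": np.arange(1, sim.S + 1),
                    "log_abundance": np.log(sim.abundances.astype(float)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run(config: AnalysisConfig) -> dict:
    """Run the configured analysis end to end; returns output paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs = {"log": log_path}
    try:
        table = read_otu_table(config.otu_path, samples_as_rows=config.samples_as_rows)
        groups = (
            read_group_map(config.groups_path, table) if config.groups_path else None
        )
        logger.info(
            "loaded %d samples x %d taxa (config %s)",
            table.n_samples,
            table.n_taxa,
            config.sha256(),
        )

        if config.community_scale.enabled:
            cs = config.community_scale
            table1 = run_community_scale(
                table,
                n_sim=cs.n_sim,
                alpha=cs.alpha,
                seed=config.seed,
                max_samples=cs.max_samples,
            )
            n_pass = int(table1["neutral"].sum())
            summary_line = (
                f"# neutral_communities={n_pass}/{len(table1)} at alpha={cs.alpha}"
            )
            path = out_dir / "table1.tsv"
            _write_report(table1, path, config, [summary_line])
            outputs["table1"] = path
            logger.info("community scale: %d/%d neutral", n_pass, len(table1))

            tested = table1[table1["error"] == ""]
            if len(tested):
                best = tested.loc[tested["p"].idxmax()]
                sad = sample_to_sad(table, best["ID"])
                ra = export_rank_abundance(
                    sad,
                    float(best["theta"]),
                    I_from_m(float(best["m"]), sad.J),
                    n_sim=config.rank_abundance_sims,
                    seed=config.seed,
                )
                ra_path = out_dir / "rank_abundance.tsv"
                _write_report(ra, ra_path, config, [f"# sample={best['ID']}"])
                outputs["rank_abundance"] = ra_path

        if config.species_scale.enabled and groups is not None:
            ss = config.species_scale
            summary, ttests, _ = run_species_scale(
                table,
                groups,
                designs=ss.designs,
                n_per_group=ss.n_per_group,
                n_repeats=ss.n_repeats,
                detection_threshold=ss.detection_threshold,
                r2_pass=ss.r2_pass,
                interval=ss.interval,
                seed=config.seed,
            )
            path = out_dir / "table2.tsv"
            _write_report(summary, path, config)
            outputs["table2"] = path
            tpath = out_dir / "ttests.tsv"
            _write_report(ttests, tpath, config)
            outputs["ttests"] = tpath

            # Per-taxon classification on the full groups (no resampling).
            frames = []
            for src, dst in ss.designs:
                fit = fit_sloan_from_table(
                    table,
                    groups.samples(src),
                    groups.samples(dst),
                    detection_threshold=ss.detection_threshold,
                    interval=ss.interval,
                )
                frame = fit.species_frame()
                frame.insert(0, "design", f"{src}->{dst}")
                frames.append(frame)
            cls_path = out_dir / "species_classification.tsv"
            _write_report(pd.concat(frames, ignore_index=True), cls_path, config)
            outputs["species_classification"] = cls_path
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs
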