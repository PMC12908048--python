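"""End-to-end pipeline: synthetic generation or file input, then
diversity → beta diversity → dysbiosis indices → cohort statistics →
prognosis → co-occurrence networks, with a manifest for reproducibility.

One global seed governs every stage through named substreams (stage name →
child seed), so toggling a stage off does not shift the draws of the others,
and re-running the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as dio
from .alpha import alpha_table
from .beta import betadisper, bray_curtis, pcoa, permanova
from .datatypes import AbundanceTable, BIOMARKERS, CohortMetadata, DysbiosisPanel, ValidationError
from .indices import age_sdi_correlation, compute_indices, derive_panel
from .network import NetworkParams, build_network, network_summary
from .prognosis import ModelSpec, bootstrap_optimism, roc_points
from .stats import biomarker_infection_correlations, group_comparison_table, plr
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("alpha", "beta", "indices", "cohort_stats", "prognosis", "network")


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Exactly one of ``synthetic`` (CohortSpec field overrides) or ``inputs``
    (paths: abundance, metadata, optionally counts and panel) must be given.
    """

    synthetic: dict | None = None
    inputs: dict | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    screen_alpha: float = 0.10
    fdr_alpha: float = 0.05
    n_perm: int = 999
    n_boot: int = 1000
    epsilon: float = 1.0
    network: dict = field(default_factory=dict)

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValidationError("exactly one of 'synthetic' or 'inputs' must be set")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.screen_alpha <= 1):
            raise ValidationError("screen_alpha must lie in (0, 1]")
        if not (0 < self.fdr_alpha <= 1):
            raise ValidationError("fdr_alpha must lie in (0, 1]")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValidationError("n_perm and n_boot must be >= 1")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(dio.read_config(path))

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _load_cohort(config: RunConfig):
    if config.synthetic is not None:
        spec = CohortSpec(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        cohort = generate_cohort(spec)
        return cohort.abundance, cohort.counts, cohort.metadata, cohort.panel()
    paths = config.inputs
    if "abundance" not in paths or "metadata" not in paths:
        raise ValidationError("inputs must provide 'abundance' and 'metadata' paths")
    abundance = dio.read_abundance(paths["abundance"], mode="relative")
    counts = dio.read_abundance(paths["counts"], mode="count") if "counts" in paths else None
    metadata = dio.read_metadata(paths["metadata"])
    panel = dio.read_panel(paths["panel"]) if "panel" in paths else None
    if abundance.sample_ids != metadata.sample_ids:
        raise ValidationError("abundance and metadata sample ids differ or are reordered")
    return abundance, counts, metadata, panel


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    abundance, counts, metadata, panel = _load_cohort(config)
    labels = metadata.infection.to_numpy()
    outputs: dict[str, list[str]] = {}

    def record(stage: str, name: str) -> Path:
        outputs.setdefault(stage, []).append(name)
        return outdir / name

    dio.write_abundance(abundance, record("input", "abundance.tsv"))
    if counts is not None:
        dio.write_abundance(counts, record("input", "counts.tsv"))
    dio.write_metadata(metadata, record("input", "metadata.csv"))

    indices_df = None

    if "alpha" in config.stages:
        dio.log_event("alpha", n_samples=abundance.n_samples)
        table = counts if counts is not None else abundance
        adf = alpha_table(table)
        adf.to_csv(record("alpha", "alpha_diversity.csv"), index_label="sample_id")
        from .stats import compare_groups

        tests = {}
        for col in adf.columns:
            cmp = compare_groups(adf[col].to_numpy(), labels, "continuous", variable=col)
            tests[col] = {"test": cmp.test, "statistic": cmp.statistic, "p_value": cmp.p_value}
        _json_dump(tests, record("alpha", "alpha_group_tests.json"))

    if "beta" in config.stages:
        dio.log_event("beta", n_perm=config.n_perm)
        dm = bray_curtis(abundance)
        dio.write_distance(dm, record("beta", "bray_curtis.tsv"))
        ord_res = pcoa(dm, k=2)
        pd.DataFrame(
            ord_res.coordinates, index=dm.sample_ids, columns=["PCo1", "PCo2"]
        ).to_csv(record("beta", "pcoa_coordinates.csv"), index_label="sample_id")
        perm = permanova(dm, labels, n_perm=config.n_perm, seed=_stage_seed(config.seed, "permanova"))
        disp = betadisper(dm, labels, n_perm=config.n_perm, seed=_stage_seed(config.seed, "betadisper"))
        _json_dump(
            {
                "permanova": dataclasses.asdict(perm),
                "betadisper": dataclasses.asdict(disp),
                "pcoa_proportion_explained": ord_res.proportion_explained.tolist(),
            },
            record("beta", "beta_tests.json"),
        )

    if "indices" in config.stages:
        dio.log_event("indices")
        used_panel = panel
        if used_panel is None:
            used_panel = derive_panel(abundance, labels, alpha=config.fdr_alpha)
        dio.write_panel(used_panel, record("indices", "panel.json"))
        indices_df = compute_indices(abundance, used_panel, epsilon=config.epsilon)
        indices_df.to_csv(record("indices", "dysbiosis_indices.csv"), index_label="sample_id")
        corr = age_sdi_correlation(metadata, indices_df, stratify="by-group")
        corr.to_csv(record("indices", "age_sdi_correlation.csv"), index=False)

    if "cohort_stats" in config.stages:
        dio.log_event("cohort_stats")
        table1 = group_comparison_table(metadata)
        table1.to_csv(record("cohort_stats", "group_comparisons.csv"))
        corr = biomarker_infection_correlations(metadata)
        corr.to_csv(record("cohort_stats", "biomarker_correlations.csv"))

    if "prognosis" in config.stages:
        dio.log_event("prognosis", n_boot=config.n_boot)
        df = metadata.data.copy()
        if "platelets" in df.columns and "lymphocytes" in df.columns:
            df["plr"] = plr(df["platelets"].to_numpy(), df["lymphocytes"].to_numpy())
        if indices_df is not None:
            df = df.join(indices_df[["sdi", "mdi"]])
        candidates = [
            c for c in ("age", "nihss", "plr", "sdi", "mdi", *BIOMARKERS) if c in df.columns
        ]
        spec = ModelSpec("infection", candidates, screen_alpha=config.screen_alpha)
        result = bootstrap_optimism(
            df, spec, n_boot=config.n_boot, seed=_stage_seed(config.seed, "bootstrap")
        )
        _json_dump(
            {
                "selected": result.selected,
                "coefficients": result.coefficients.round(10).to_dict(orient="index"),
                "apparent_auc": result.apparent_auc,
                "optimism": result.optimism,
                "corrected_auc": result.corrected_auc,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "n_boot": result.n_boot,
                "n_redraws": result.n_redraws,
                "penalized": result.penalized,
            },
            record("prognosis", "prognosis.json"),
        )
        if result.selected:
            from .prognosis import fit_logistic

            fit = fit_logistic(df, "infection", result.selected)
            scores = fit.predict(df[result.selected].to_numpy(dtype=float))
            roc_points(scores, labels).to_csv(record("prognosis", "roc_points.csv"), index=False)

    if "network" in config.stages:
        dio.log_event("network")
        params = NetworkParams(fdr_alpha=config.fdr_alpha, **config.network)
        summaries = {}
        for name, mask in (("infected", labels == 1), ("non_infected", labels == 0)):
            net = build_network(abundance, sample_mask=mask, params=params)
            net.edges.to_csv(record("network", f"network_edges_{name}.tsv"), sep="\t", index=False)
            summaries[name] = network_summary(net) | {"tested_pairs": net.tested_pairs}
        summaries["parameters"] = dataclasses.asdict(params)
        _json_dump(summaries, record("network", "network_summary.json"))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.canonical(),
        "config_hash": config.config_hash(),
        "stages": {k: sorted(v) for k, v in outputs.items()},
    }
    _json_dump(manifest, outdir / "manifest.json")
    return manifest
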