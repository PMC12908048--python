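"""Synthetic post-stroke infection cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: two groups (infected / non-infected), compositional taxa abundances
with Dirichlet-scale enrichment of opportunistic pathogens and depletion of
SCFA producers in the infected group, log-normal serum biomarkers whose
group medians and quartiles match clinically reported values, and the usual
clinical covariates (age, sex, NIHSS, blood counts).

Biomarker distributions are parameterised from (median, Q1, Q3) triples: the
log-normal mu is pinned to ln(median) and sigma is the least-squares fit to
the two log-scale quartiles, which has the closed form
``(ln q3 - ln q1) / (2 z_0.75)``.

Randomness flows through named substreams derived from one global seed, so
adding a variable to the generator does not perturb existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceTable, CohortMetadata, DysbiosisPanel, ValidationError

__all__ = [
    "BiomarkerParams",
    "CohortSpec",
    "SyntheticCohort",
    "DEFAULT_BIOMARKER_PARAMS",
    "default_panel",
    "generate_cohort",
    "solve_lognormal_from_median_iqr",
    "sample_lognormal_from_median_iqr",
]

_Z75 = stats.norm.ppf(0.75)


@dataclass(frozen=True)
class BiomarkerParams:
    """Group-wise median and quartiles of one biomarker, in assay units."""

    median_infected: float
    iqr_infected: tuple[float, float]
    median_noninfected: float
    iqr_noninfected: tuple[float, float]
    unit: str = ""


# Reported serum biomarker medians (Q1–Q3) by infection status in an acute
# ischemic stroke cohort; units are opaque labels as far as the generator is
# concerned.
DEFAULT_BIOMARKER_PARAMS: dict[str, BiomarkerParams] = {
    "nmdar": BiomarkerParams(3.99, (3.28, 9.20), 1.23, (0.82, 2.67), "ng/mL"),
    "butyrate": BiomarkerParams(7.59, (4.16, 9.74), 13.22, (11.81, 15.56), "ng/mL"),
    "tmao": BiomarkerParams(636.46, (569.08, 691.52), 396.22, (299.13, 478.63), "ng/mL"),
    "rankl": BiomarkerParams(4.51, (3.92, 5.53), 43.92, (6.40, 83.09), "pg/mL"),
    "ifabp": BiomarkerParams(4.35, (3.43, 5.57), 2.43, (1.79, 3.02), "pg/mL"),
    "lps": BiomarkerParams(190.80, (14.01, 251.93), 83.00, (63.94, 122.00), "pg/mL"),
}

# Readable default taxon names for the planted panel; purely cosmetic.
_PATHOGENIC_NAMES = [
    "Klebsiella_pneumoniae",
    "Escherichia_coli",
    "Salmonella_enterica",
    "Enterobacter_cloacae",
    "Streptococcus_anginosus",
    "Proteus_mirabilis",
    "Citrobacter_freundii",
    "Enterococcus_faecalis",
    "Morganella_morganii",
    "Serratia_marcescens",
]
_BENEFICIAL_NAMES = [
    "Faecalibacterium_prausnitzii",
    "Blautia_wexlerae",
    "Agathobacter_rectalis",
    "Roseburia_intestinalis",
    "Eubacterium_rectale",
    "Anaerostipes_hadrus",
    "Coprococcus_comes",
    "Ruminococcus_bromii",
    "Dorea_longicatena",
    "Fusicatenibacter_saccharivorans",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    Defaults reproduce the study conditions: 80 patients with 37 infected,
    older infected patients (67.2 ± 10.4 vs 57.8 ± 11.6 years), biomarker
    medians/IQRs from the reported laboratory table, enrichment of
    Enterobacteriaceae-type taxa (fold 4) and depletion of SCFA producers
    (fold 0.25) in the infected group.
    """

    n_total: int = 80
    n_infected: int = 37
    n_taxa: int = 150
    n_pathogenic: int = 10
    n_beneficial: int = 10
    pathogenic_fold_change: float = 4.0
    beneficial_fold_change: float = 0.25
    biomarker_params: dict[str, BiomarkerParams] = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_PARAMS)
    )
    age_params: tuple[tuple[float, float], tuple[float, float]] = ((67.2, 10.4), (57.8, 11.6))
    seed: int = 0
    depth: int = 10_000
    # Dirichlet concentration mass: larger -> less sample-to-sample variation.
    total_concentration: float = 50.0
    # Baseline compositional share of the planted panels; pathogens are rare,
    # SCFA producers abundant, so fold changes survive renormalisation.
    pathogenic_share: float = 0.02
    beneficial_share: float = 0.12
    male_fraction: tuple[float, float] = (0.459, 0.698)  # (infected, non-infected)
    dysphagia_fraction: tuple[float, float] = (0.297, 0.116)
    # Log-sd of a shared per-sample "guild activity" factor multiplying the
    # beneficial (SCFA-producer) concentrations in the non-infected group
    # only. It induces positive co-occurrence among those taxa — the
    # cooperative network structure that collapses under infection. 0 disables.
    guild_sigma: float = 0.6

    def validate(self) -> None:
        if self.n_total <= 0:
            raise ValidationError("n_total must be positive")
        if not (0 < self.n_infected <= self.n_total):
            raise ValidationError("n_infected must satisfy 0 < n_infected <= n_total")
        if self.n_pathogenic + self.n_beneficial > self.n_taxa:
            raise ValidationError("n_pathogenic + n_beneficial must not exceed n_taxa")
        if self.n_pathogenic <= 0 or self.n_beneficial <= 0:
            raise ValidationError("n_pathogenic and n_beneficial must be positive")
        if self.pathogenic_fold_change <= 0:
            raise ValidationError("pathogenic_fold_change must be > 0")
        if self.beneficial_fold_change <= 0:
            raise ValidationError("beneficial_fold_change must be > 0")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.total_concentration <= 0:
            raise ValidationError("total_concentration must be positive")
        if not (0 < self.pathogenic_share + self.beneficial_share < 1):
            raise ValidationError("panel shares must sum to a value in (0, 1)")
        for name, p in self.biomarker_params.items():
            for median, (q1, q3) in (
                (p.median_infected, p.iqr_infected),
                (p.median_noninfected, p.iqr_noninfected),
            ):
                if not (0 < q1 < median < q3):
                    raise ValidationError(
                        f"biomarker_params[{name!r}]: need 0 < q1 < median < q3, "
                        f"got q1={q1}, median={median}, q3={q3}"
                    )
        for mean, sd in self.age_params:
            if sd <= 0:
                raise ValidationError("age_params sd must be > 0")


@dataclass
class SyntheticCohort:
    """Generated cohort: relative + count abundance tables, metadata, and the
    true per-taxon group-effect multipliers used in generation."""

    abundance: AbundanceTable
    counts: AbundanceTable
    metadata: CohortMetadata
    truth: dict[str, float]
    spec: CohortSpec

    @property
    def pathogenic_taxa(self) -> list[str]:
        path, _, _ = _taxon_names(self.spec)
        return path

    @property
    def beneficial_taxa(self) -> list[str]:
        _, bene, _ = _taxon_names(self.spec)
        return bene

    def panel(self) -> DysbiosisPanel:
        """Unit-weight panel of the planted enriched/depleted taxa."""
        return DysbiosisPanel(
            enriched={t: 1.0 for t in self.pathogenic_taxa},
            depleted={t: 1.0 for t in self.beneficial_taxa},
            level="species",
        )


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: one global seed, independent stream per variable."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def solve_lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) from a (median, Q1, Q3) summary.

    mu is pinned to ``ln(median)``; sigma is the least-squares fit to the two
    log-scale quartiles, which reduces to ``(ln q3 - ln q1) / (2 z_0.75)``.
    When the printed quartiles are asymmetric on the log scale the model
    quartiles carry a symmetric residual around them.
    """
    if not (0 < q1 < median < q3):
        raise ValidationError(f"need 0 < q1 < median < q3, got q1={q1}, median={median}, q3={q3}")
    mu = float(np.log(median))
    sigma = float((np.log(q3) - np.log(q1)) / (2.0 * _Z75))
    return mu, sigma


def sample_lognormal_from_median_iqr(
    median: float, q1: float, q3: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    mu, sigma = solve_lognormal_from_median_iqr(median, q1, q3)
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


def _taxon_names(spec: CohortSpec) -> tuple[list[str], list[str], list[str]]:
    path = [
        _PATHOGENIC_NAMES[i] if i < len(_PATHOGENIC_NAMES) else f"pathogen_{i:03d}"
        for i in range(spec.n_pathogenic)
    ]
    bene = [
        _BENEFICIAL_NAMES[i] if i < len(_BENEFICIAL_NAMES) else f"scfa_producer_{i:03d}"
        for i in range(spec.n_beneficial)
    ]
    n_rest = spec.n_taxa - spec.n_pathogenic - spec.n_beneficial
    rest = [f"taxon_{i:03d}" for i in range(n_rest)]
    return path, bene, rest


def generate_cohort(spec: CohortSpec | None = None, **overrides) -> SyntheticCohort:
    """Draw one cohort. Deterministic for a fixed ``spec.seed``."""
    if spec is None:
        spec = CohortSpec()
    if overrides:
        spec = replace(spec, **overrides)
    spec.validate()

    path_names, bene_names, rest_names = _taxon_names(spec)
    taxa = path_names + bene_names + rest_names
    n, t = spec.n_total, spec.n_taxa
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    # --- infection labels: n_infected ones, shuffled under the seed --------
    labels = np.zeros(n, dtype=int)
    labels[: spec.n_infected] = 1
    labels = _rng(spec.seed, "labels").permutation(labels)
    infected = labels == 1

    # --- baseline Dirichlet concentrations --------------------------------
    rng_taxa = _rng(spec.seed, "taxa")
    base = rng_taxa.lognormal(mean=0.0, sigma=1.0, size=t)
    is_path = np.zeros(t, dtype=bool)
    is_path[: spec.n_pathogenic] = True
    is_bene = np.zeros(t, dtype=bool)
    is_bene[spec.n_pathogenic : spec.n_pathogenic + spec.n_beneficial] = True
    is_rest = ~(is_path | is_bene)
    # panel taxa are consistently detectable organisms by construction, so
    # their baseline spread is tighter than the filler tail
    panel_mask = is_path | is_bene
    base[panel_mask] = rng_taxa.lognormal(mean=0.0, sigma=0.5, size=int(panel_mask.sum()))
    # fix the baseline compositional shares of the three blocks
    share_rest = 1.0 - spec.pathogenic_share - spec.beneficial_share
    for mask, share in ((is_path, spec.pathogenic_share), (is_bene, spec.beneficial_share), (is_rest, share_rest)):
        if mask.any():
            base[mask] *= share / base[mask].sum()
    conc = base * spec.total_concentration

    fold = np.ones(t)
    fold[is_path] = spec.pathogenic_fold_change
    fold[is_bene] = spec.beneficial_fold_change

    conc_matrix = np.tile(conc, (n, 1))
    conc_matrix[infected] *= fold

    if spec.guild_sigma > 0:
        # mean-one activity; non-beneficial taxa absorb the complementary
        # mass so every taxon's expected share is preserved exactly
        rng_guild = _rng(spec.seed, "guild")
        activity = rng_guild.lognormal(-spec.guild_sigma**2 / 2, spec.guild_sigma, n)
        activity = np.minimum(activity, 0.8 / spec.beneficial_share)
        comp = (1.0 - spec.beneficial_share * activity) / (1.0 - spec.beneficial_share)
        guild = np.where(is_bene[None, :], activity[:, None], comp[:, None])
        guild[infected] = 1.0  # guild disrupted under infection
        conc_matrix *= guild

    # Dirichlet via normalised gammas (vectorised across samples)
    rng_ab = _rng(spec.seed, "abundance")
    gammas = rng_ab.standard_gamma(conc_matrix)
    rel = gammas / gammas.sum(axis=1, keepdims=True)

    rng_counts = _rng(spec.seed, "counts")
    counts = rng_counts.multinomial(spec.depth, rel)

    abundance = AbundanceTable(pd.DataFrame(rel, index=sample_ids, columns=taxa), "relative")
    count_table = AbundanceTable(pd.DataFrame(counts, index=sample_ids, columns=taxa), "count")

    # --- metadata ----------------------------------------------------------
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    meta["infection"] = labels

    (mean_inf, sd_inf), (mean_non, sd_non) = spec.age_params
    age = np.empty(n)
    rng_age = _rng(spec.seed, "age")
    age[infected] = rng_age.normal(mean_inf, sd_inf, infected.sum())
    age[~infected] = rng_age.normal(mean_non, sd_non, (~infected).sum())
    meta["age"] = np.clip(age, 18.0, None).round(1)

    rng_sex = _rng(spec.seed, "sex")
    p_male = np.where(infected, spec.male_fraction[0], spec.male_fraction[1])
    meta["sex"] = np.where(rng_sex.random(n) < p_male, "male", "female")

    # NIHSS: 4 + Poisson tail, slightly heavier in the infected group, giving
    # group medians near the reported 5 vs 4.
    rng_nihss = _rng(spec.seed, "nihss")
    lam = np.where(infected, 1.2, 0.6)
    meta["nihss"] = 4 + rng_nihss.poisson(lam)

    # Blood counts (cells/uL): log-normal; lower lymphocytes in the infected
    # group so PLR is elevated there.
    rng_plt = _rng(spec.seed, "platelets")
    meta["platelets"] = rng_plt.lognormal(np.log(250_000.0), 0.25, n).round(0)
    rng_lym = _rng(spec.seed, "lymphocytes")
    lym_median = np.where(infected, 1_400.0, 1_950.0)
    meta["lymphocytes"] = rng_lym.lognormal(np.log(lym_median), 0.35, n).round(0)

    for name, p in spec.biomarker_params.items():
        rng_b = _rng(spec.seed, f"biomarker:{name}")
        vals = np.empty(n)
        # fixed substream order: infected block first, then non-infected
        vals[infected] = sample_lognormal_from_median_iqr(
            p.median_infected, *p.iqr_infected, size=int(infected.sum()), rng=rng_b
        )
        vals[~infected] = sample_lognormal_from_median_iqr(
            p.median_noninfected, *p.iqr_noninfected, size=int((~infected).sum()), rng=rng_b
        )
        meta[name] = vals

    rng_dys = _rng(spec.seed, "dysphagia")
    p_dys = np.where(infected, spec.dysphagia_fraction[0], spec.dysphagia_fraction[1])
    meta["dysphagia"] = (rng_dys.random(n) < p_dys).astype(int)

    truth = dict(zip(taxa, fold))
    return SyntheticCohort(abundance, count_table, CohortMetadata(meta), truth, spec)


def default_panel() -> DysbiosisPanel:
    """Unit-weight panel over the default generator taxa."""
    return DysbiosisPanel(
        enriched={t: 1.0 for t in _PATHOGENIC_NAMES},
        depleted={t: 1.0 for t in _BENEFICIAL_NAMES},
        level="species",
    )
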