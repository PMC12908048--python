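"""SDI/MDI formula checks, panel derivation and the age correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dysbiom import (
    AbundanceTable,
    CohortMetadata,
    CohortSpec,
    DysbiosisPanel,
    ValidationError,
    age_sdi_correlation,
    compute_indices,
    derive_panel,
    generate_cohort,
    mdi,
    sdi,
)
from dysbiom.indices import panel_coverage

from conftest import random_relative_table


def sample_from(**abunds) -> pd.Series:
    return pd.Series(abunds, dtype=float)


class TestMdi:
    def test_symmetric_sums_zero(self, small_panel):
        s = sample_from(A=0.1, B=0.1, C=0.15, D=0.05, E=0.6)
        assert mdi(s, small_panel) == pytest.approx(0.0)

    def test_hand_value(self, small_panel):
        s = sample_from(A=0.03, B=0.01, C=0.2, D=0.04, E=0.72)
        assert mdi(s, small_panel) == pytest.approx(np.log10(1.04 / 1.24), abs=1e-12)
        assert mdi(s, small_panel) == pytest.approx(-0.076388, abs=1e-6)

    def test_bounds_for_relative_abundances(self, rng, small_panel):
        for _ in range(100):
            v = rng.dirichlet(np.ones(5))
            s = pd.Series(v, index=list("ABCDE"))
            val = mdi(s, small_panel)
            assert -np.log10(2) <= val <= np.log10(2)

    def test_count_mode_input_rejected(self, small_panel):
        s = sample_from(A=40.0, B=10.0, C=30.0, D=20.0)
        with pytest.raises(ValidationError, match="relative"):
            mdi(s, small_panel)

    def test_missing_panel_taxon_counts_as_zero(self, small_panel):
        s = sample_from(A=0.3, C=0.3, E=0.4)  # B, D absent
        assert mdi(s, small_panel) == pytest.approx(np.log10(1.3 / 1.3))


class TestSdi:
    def test_reduces_to_mdi_with_unit_weights(self, rng, small_panel):
        for _ in range(50):
            v = rng.dirichlet(np.ones(5))
            s = pd.Series(v, index=list("ABCDE"))
            assert sdi(s, small_panel, epsilon=1.0) == mdi(s, small_panel)

    def test_weighted_hand_value(self):
        panel = DysbiosisPanel(enriched={"A": 2.0}, depleted={"B": 1.0})
        s = sample_from(A=0.1, B=0.05, E=0.85)
        expected = np.log10((1e-6 + 0.2) / (1e-6 + 0.05))
        assert sdi(s, panel, epsilon=1e-6) == pytest.approx(expected, abs=1e-9)
        assert sdi(s, panel, epsilon=1e-6) == pytest.approx(0.602052, abs=1e-5)

    def test_nonpositive_epsilon_rejected(self, small_panel):
        with pytest.raises(ValidationError, match="epsilon"):
            sdi(sample_from(A=0.5, C=0.5), small_panel, epsilon=0.0)

    def test_zeroed_panel_abundances_give_zero(self, small_panel):
        s = sample_from(A=0.0, B=0.0, C=0.0, D=0.0, E=1.0)
        assert sdi(s, small_panel, epsilon=1.0) == 0.0
        assert mdi(s, small_panel) == 0.0

    def test_monotone_in_enriched_abundance(self, small_panel):
        lo = sample_from(A=0.05, B=0.1, C=0.2, D=0.1, E=0.55)
        hi = sample_from(A=0.15, B=0.1, C=0.2, D=0.1, E=0.45)
        assert sdi(hi, small_panel) > sdi(lo, small_panel)
        assert mdi(hi, small_panel) > mdi(lo, small_panel)


class TestComputeIndices:
    def test_table_output_and_coverage(self, default_cohort):
        panel = default_cohort.panel()
        out = compute_indices(default_cohort.abundance, panel)
        assert list(out.columns) == ["sdi", "mdi", "panel_coverage"]
        assert np.isfinite(out[["sdi", "mdi"]].to_numpy()).all()
        assert (out["panel_coverage"] == 1.0).all()

    def test_partial_coverage(self, rng, small_panel):
        table = random_relative_table(rng, 4, 3)  # taxa t0..t2, none in panel
        table.data.columns = ["A", "t1", "t2"]
        assert panel_coverage(table, small_panel) == 0.25

    def test_count_table_rejected(self, default_cohort):
        with pytest.raises(ValidationError, match="relative"):
            compute_indices(default_cohort.counts, default_cohort.panel())


class TestDerivePanel:
    def test_planted_strong_shift_lands_enriched_with_weight_one(self, rng):
        n = 60
        base = rng.dirichlet(np.ones(6) * 10, size=n)
        vals = base.copy()
        lab = np.array([0] * 30 + [1] * 30)
        vals[lab == 1, 0] *= 10  # strong upward shift of taxon 0 in cases
        vals /= vals.sum(axis=1, keepdims=True)
        table = AbundanceTable(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(n)],
                         columns=[f"t{j}" for j in range(6)]),
            "relative",
        )
        panel = derive_panel(table, lab, alpha=0.05)
        assert "t0" in panel.enriched
        assert panel.enriched["t0"] == pytest.approx(1.0)

    def test_null_table_raises_empty_panel(self):
        empties = 0
        for rep in range(50):
            r = np.random.default_rng(900 + rep)
            vals = r.dirichlet(np.ones(10), size=20)
            table = AbundanceTable(
                pd.DataFrame(vals, index=[f"s{i}" for i in range(20)],
                             columns=[f"t{j}" for j in range(10)]),
                "relative",
            )
            try:
                derive_panel(table, [0] * 10 + [1] * 10, alpha=0.05)
            except ValidationError as exc:
                assert "empty" in str(exc)
                empties += 1
        assert empties >= 45  # >=90% of null replicates produce no panel

    def test_alpha_one_assigns_every_taxon(self, default_cohort):
        lab = default_cohort.metadata.infection.to_numpy()
        panel = derive_panel(default_cohort.abundance, lab, alpha=1.0)
        n_assigned = len(panel.enriched) + len(panel.depleted)
        assert n_assigned == default_cohort.abundance.n_taxa

    def test_too_few_samples_rejected(self, rng):
        table = random_relative_table(rng, 5, 4)
        with pytest.raises(ValidationError, match="3 samples"):
            derive_panel(table, [0, 0, 1, 1, 1])


class TestAgeSdiCorrelation:
    def _meta(self, age, infection):
        return CohortMetadata(
            pd.DataFrame({"infection": infection, "age": age},
                         index=[f"s{i}" for i in range(len(age))])
        )

    def _idx(self, sdi_vals, n):
        return pd.DataFrame({"sdi": sdi_vals}, index=[f"s{i}" for i in range(n)])

    def test_monotone_gives_rho_one(self):
        n = 8
        meta = self._meta(np.arange(n, dtype=float) + 50, [0, 1] * 4)
        res = age_sdi_correlation(meta, self._idx(np.linspace(-1, 1, n), n), "pooled")
        assert res.loc[res.stratum == "pooled", "rho"].iloc[0] == pytest.approx(1.0)

    def test_simpson_reversal_pooled_exceeds_within(self):
        """Two clusters shifted in both age and SDI: pooled rho exceeds both
        within-group rhos."""
        r = np.random.default_rng(7)
        n = 20
        age0 = r.normal(55, 3, n)
        age1 = r.normal(70, 3, n)
        sdi0 = r.normal(-0.3, 0.2, n)
        sdi1 = r.normal(0.3, 0.2, n)
        meta = self._meta(np.r_[age0, age1], [0] * n + [1] * n)
        res = age_sdi_correlation(meta, self._idx(np.r_[sdi0, sdi1], 2 * n), "by-group")
        pooled = res.loc[res.stratum == "pooled", "rho"].iloc[0]
        within = res.loc[res.stratum != "pooled", "rho"]
        assert pooled > within.abs().max()

    def test_constant_age_rejected(self):
        meta = self._meta([60.0] * 6, [0, 0, 0, 1, 1, 1])
        with pytest.raises(ValidationError, match="constant age"):
            age_sdi_correlation(meta, self._idx(np.linspace(0, 1, 6), 6), "pooled")

    def test_small_stratum_rejected(self):
        meta = self._meta([50, 60, 70, 55, 65], [0, 0, 0, 0, 1])
        # infected stratum has 1 sample (also fails the >=4 rule)
        with pytest.raises(ValidationError, match="fewer than 4"):
            age_sdi_correlation(meta, self._idx(np.linspace(0, 1, 5), 5), "by-group")

    def test_null_correlation_small(self, default_cohort):
        """Independent age and SDI give small |rho| on a large sample."""
        c = generate_cohort(CohortSpec(seed=9, n_total=400, n_infected=200,
                                       pathogenic_fold_change=1.0, beneficial_fold_change=1.0))
        idx = compute_indices(c.abundance, c.panel())
        res = age_sdi_correlation(c.metadata, idx, "pooled")
        assert abs(res.loc[res.stratum == "pooled", "rho"].iloc[0]) < 0.15
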