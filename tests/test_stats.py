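"""Tests of the cohort-level statistics (rank tests, regressions, LRT)."""

import numpy as np
import pandas as pd
import pytest

from entroseq.signature import EntropyResult
from entroseq.stats import (
    SIZE_TRANSFORMS,
    compare_classes,
    lrt_nested,
    paired_gene_set_compare,
    phylum_model,
    regress_at_on_dkl_and_size,
    regress_dkl_on_at,
    regress_size_on_at,
    welch_two_groups,
)


def table_from(**cols) -> pd.DataFrame:
    return pd.DataFrame(cols)


def entropy_rows(ids, dkls) -> list[EntropyResult]:
    return [EntropyResult(i, d, 1.0, 0.5, 0.5, 10_000, 9_997)
            for i, d in zip(ids, dkls)]


class TestCompareClasses:
    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(0.1, 1.0, 10))
        t = table_from(id=[f"s{i}" for i in range(20)],
                       **{"class": ["chromosome"] * 10 + ["plasmid"] * 10},
                       dkl=vals + vals)
        out = compare_classes(t)
        row = out.iloc[0]
        assert row["p_value"] > 0.9
        assert row["direction"] == "none"

    def test_all_pairs_reported_in_canonical_order(self, rng):
        t = table_from(
            id=[f"s{i}" for i in range(40)],
            **{"class": np.repeat(["plasmid", "phage", "island",
                                   "chromosome"], 10)},
            dkl=rng.uniform(0, 1, 40))
        out = compare_classes(t)
        assert len(out) == 6
        assert list(out.columns[:2]) == ["class_a", "class_b"]
        assert out.iloc[0][["class_a", "class_b"]].tolist() == \
            ["chromosome", "island"]

    def test_small_class_excluded_with_warning(self, rng, caplog):
        t = table_from(id=[f"s{i}" for i in range(23)],
                       **{"class": ["chromosome"] * 10 + ["phage"] * 10
                          + ["plasmid"] * 3},
                       dkl=rng.uniform(0, 1, 23))
        with caplog.at_level("WARNING"):
            out = compare_classes(t)
        assert len(out) == 1
        assert "plasmid" in caplog.text

    def test_separated_groups_detected_with_direction(self, rng):
        t = table_from(id=[f"s{i}" for i in range(30)],
                       **{"class": ["chromosome"] * 15 + ["plasmid"] * 15},
                       dkl=np.r_[rng.normal(1.5, 0.1, 15),
                                 rng.normal(0.5, 0.1, 15)])
        row = compare_classes(t).iloc[0]
        assert row["p_value"] < 0.001
        assert row["direction"] == ">"

    def test_holm_adjustment_monotone(self, rng):
        t = table_from(
            id=[f"s{i}" for i in range(40)],
            **{"class": np.repeat(["chromosome", "island", "phage",
                                   "plasmid"], 10)},
            dkl=np.r_[rng.normal(2, 0.2, 10), rng.normal(1.5, 0.2, 10),
                      rng.normal(1.0, 0.2, 10), rng.normal(0.5, 0.2, 10)])
        out = compare_classes(t, holm=True)
        assert np.all(out["p_holm"] >= out["p_value"] - 1e-15)
        assert np.all(out["p_holm"] <= 1.0)


class TestRegressDklOnAt:
    def test_noiseless_linear_recovery(self):
        at = np.linspace(0.3, 0.7, 20)
        t = table_from(id=range(20), dkl=np.exp(2 - 3 * at), at_content=at)
        rep = regress_dkl_on_at(t)
        assert rep.params["at_content"] == pytest.approx(-3.0, abs=1e-10)
        assert rep.params["Intercept"] == pytest.approx(2.0, abs=1e-10)
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_zero_dkl_rows_dropped_with_warning(self, caplog):
        at = np.linspace(0.3, 0.7, 15)
        dkl = np.exp(1 - 2 * at)
        dkl[0] = 0.0
        t = table_from(id=range(15), dkl=dkl, at_content=at)
        with caplog.at_level("WARNING"):
            rep = regress_dkl_on_at(t)
        assert rep.n == 14
        assert "dkl <= 0" in caplog.text

    def test_shuffled_pairing_has_no_signal(self):
        r2 = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            at = rng.uniform(0.3, 0.7, 60)
            dkl = np.exp(2 - 3 * rng.permutation(at)
                         + rng.normal(0, 0.1, 60))
            t = table_from(id=range(60), dkl=dkl, at_content=at)
            r2.append(regress_dkl_on_at(t).r_squared)
        assert np.mean(r2) < 0.05


class TestRegressSizeOnAt:
    def test_noiseless_sqrt_recovery_for_chromosomes(self):
        at = np.linspace(0.3, 0.7, 20)
        t = table_from(id=range(20), **{"class": ["chromosome"] * 20},
                       length=(5000 - 3000 * at) ** 2, at_content=at)
        rep = regress_size_on_at(t, "chromosome")
        assert rep.response_transform == "sqrt"
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)
        assert rep.params["at_content"] == pytest.approx(-3000, abs=1e-6)

    def test_independent_size_gives_no_signal(self):
        rng = np.random.default_rng(1)
        t = table_from(id=range(200), **{"class": ["island"] * 200},
                       length=rng.integers(10_001, 100_000, 200),
                       at_content=rng.uniform(0.3, 0.7, 200))
        assert regress_size_on_at(t, "island").r_squared < 0.05

    def test_transform_registry_is_total(self):
        assert set(SIZE_TRANSFORMS) == {"chromosome", "island", "phage",
                                        "plasmid"}
        names = {cls: SIZE_TRANSFORMS[cls][0] for cls in SIZE_TRANSFORMS}
        assert names == {"chromosome": "sqrt", "phage": "log",
                         "plasmid": "log", "island": "reciprocal"}

    def test_nonpositive_size_excluded(self, caplog):
        t = table_from(id=range(12), **{"class": ["island"] * 12},
                       length=[0] + [20_000] * 11,
                       at_content=np.linspace(0.3, 0.7, 12))
        with caplog.at_level("WARNING"):
            rep = regress_size_on_at(t, "island")
        assert rep.n == 11

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            regress_size_on_at(table_from(id=[1], **{"class": ["gene"]},
                                          length=[1], at_content=[0.5]),
                               "gene")


class TestCombinedAtModel:
    def test_additive_effects_decompose(self):
        rng = np.random.default_rng(2)
        n = 200
        dkl = rng.uniform(0.5, 2.0, n)
        size = rng.uniform(1e5, 5e6, n)
        at = 0.5 - 0.1 * (dkl - dkl.mean()) - 4e-8 * (size - size.mean()) \
            + rng.normal(0, 0.01, n)
        t = table_from(id=range(n), dkl=dkl, length=size, at_content=at)
        rep = regress_at_on_dkl_and_size(t)
        assert rep.extra["r2_size_only"] > 0.05
        assert rep.extra["r2_incremental_dkl"] > 0.05
        assert rep.r_squared == pytest.approx(
            rep.extra["r2_size_only"] + rep.extra["r2_incremental_dkl"])

    def test_constant_response_degenerates_to_zero(self):
        rng = np.random.default_rng(3)
        t = table_from(id=range(30), dkl=rng.uniform(0, 1, 30),
                       length=rng.uniform(1e4, 1e6, 30),
                       at_content=np.full(30, 0.5))
        rep = regress_at_on_dkl_and_size(t)
        assert rep.r_squared == pytest.approx(0.0, abs=1e-12)
        for name in ("dkl", "size_c", "size_c2"):
            assert rep.params[name] == pytest.approx(0.0, abs=1e-12)

    def test_permuted_dkl_adds_nothing(self):
        incr = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 80
            size = rng.uniform(1e5, 5e6, n)
            at = 0.5 - 4e-8 * (size - size.mean()) + rng.normal(0, 0.02, n)
            t = table_from(id=range(n), dkl=rng.permutation(n) / n,
                           length=size, at_content=at)
            incr.append(regress_at_on_dkl_and_size(t)
                        .extra["r2_incremental_dkl"])
        assert np.mean(incr) < 0.05


class TestLrtNested:
    @staticmethod
    def _noise_table(rng, n=50):
        return table_from(dkl=rng.normal(1, 0.2, n),
                          at_content=rng.uniform(0.3, 0.7, n),
                          noise=rng.normal(0, 1, n))

    def test_identical_models_give_unit_p(self, rng):
        t = self._noise_table(rng)
        stat, p = lrt_nested(t, "dkl ~ at_content", "dkl ~ at_content")
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0

    def test_non_nested_rejected(self, rng):
        with pytest.raises(ValueError, match="not nested"):
            lrt_nested(self._noise_table(rng), "dkl ~ at_content",
                       "dkl ~ noise")

    def test_active_predictor_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            at = rng.uniform(0.3, 0.7, n)
            t = table_from(dkl=1.0 - 1.5 * at + rng.normal(0, 0.1, n),
                           at_content=at)
            _, p = lrt_nested(t, "dkl ~ at_content", "dkl ~ 1")
            hits += p < 0.05
        assert hits >= 18

    def test_type_one_error_calibrated(self):
        """Adding a pure-noise predictor rejects at ~5%."""
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            t = self._noise_table(rng)
            _, p = lrt_nested(t, "dkl ~ at_content + noise",
                              "dkl ~ at_content")
            rejections += p < 0.05
        assert 0.01 < rejections / 100 < 0.12


class TestPhylumModel:
    def test_distinct_phyla_with_constant_gc(self, rng):
        n = 100
        t = table_from(dkl=np.r_[rng.normal(1.5, 0.1, n),
                                 rng.normal(0.8, 0.1, n)],
                       phylum=["p1"] * n + ["p2"] * n,
                       gc_content=rng.uniform(0.49, 0.51, 2 * n))
        out = phylum_model(t)
        assert out["r2_phylum"] > 0.8
        assert out["r2_gc"] < 0.05

    def test_permuted_labels_have_no_signal(self):
        r2 = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = table_from(dkl=rng.normal(1, 0.2, 60),
                           phylum=rng.permutation(["p1"] * 30 + ["p2"] * 30),
                           gc_content=rng.uniform(0.3, 0.7, 60))
            r2.append(phylum_model(t)["r2_phylum"])
        assert np.mean(r2) < 0.05

    def test_additive_independent_effects_sum(self, rng):
        n = 4000
        phylum = rng.permutation(["p1"] * (n // 2) + ["p2"] * (n // 2))
        gc = rng.uniform(0.3, 0.7, n)
        dkl = 1.0 + 0.4 * (phylum == "p2") + 1.2 * (gc - 0.5) \
            + rng.normal(0, 0.15, n)
        t = table_from(dkl=dkl, phylum=phylum, gc_content=gc)
        out = phylum_model(t)
        assert out["r2_combined"] == pytest.approx(
            out["r2_phylum"] + out["r2_gc"], abs=0.05)
        assert out["interaction_p"] > 0.01  # no constructed interaction

    def test_single_phylum_rejected(self, rng):
        t = table_from(dkl=rng.normal(1, 0.1, 20), phylum=["p1"] * 20,
                       gc_content=rng.uniform(0.3, 0.7, 20))
        with pytest.raises(ValueError, match="phyla"):
            phylum_model(t)


class TestWelch:
    def test_identical_groups(self):
        vals = list(np.linspace(0.5, 1.5, 10))
        t = table_from(dkl=vals * 2, domain=["bacteria"] * 10
                       + ["archaea"] * 10)
        _, p = welch_two_groups(t)
        assert p > 0.99

    def test_separated_groups(self, rng):
        t = table_from(dkl=np.r_[rng.normal(1.5, 0.1, 20),
                                 rng.normal(0.8, 0.1, 20)],
                       domain=["bacteria"] * 20 + ["archaea"] * 20)
        stat, p = welch_two_groups(t)
        assert p < 0.01

    def test_missing_group_rejected(self, rng):
        t = table_from(dkl=rng.normal(1, 0.1, 10), domain=["bacteria"] * 10)
        with pytest.raises(ValueError, match="exactly 2"):
            welch_two_groups(t)


class TestPairedGeneSets:
    def test_identical_sets_give_null_result(self):
        a = entropy_rows([f"a{i}" for i in range(20)], np.linspace(0.5, 2, 20))
        b = entropy_rows([f"b{i}" for i in range(20)], np.linspace(0.5, 2, 20))
        pairing = {x.id: y.id for x, y in zip(a, b)}
        row = paired_gene_set_compare(a, b, pairing)
        assert row["median_diff"] == 0.0
        assert row["p_value"] == pytest.approx(1.0)
        assert row["direction"] == "none"

    def test_shifted_set_detected(self, rng):
        dkl = rng.uniform(0.5, 2.0, 30)
        a = entropy_rows([f"a{i}" for i in range(30)], dkl)
        b = entropy_rows([f"b{i}" for i in range(30)],
                         dkl - rng.uniform(0.05, 0.3, 30))
        pairing = {x.id: y.id for x, y in zip(a, b)}
        row = paired_gene_set_compare(a, b, pairing)
        assert row["p_value"] < 0.001
        assert row["direction"] == "a>b"

    def test_broken_pairing_lists_offenders(self):
        a = entropy_rows(["a0", "a1"] + [f"a{i}" for i in range(2, 12)],
                         np.ones(12))
        b = entropy_rows([f"b{i}" for i in range(12)], np.ones(12))
        pairing = {x.id: y.id for x, y in zip(a, b)}
        pairing["a_missing"] = pairing.pop("a0")
        with pytest.raises(ValueError, match="a_missing"):
            paired_gene_set_compare(a, b, pairing)
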