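import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from osmacnet.chemspace import (
    UndefinedFoldChangeError,
    bin_fold_changes,
    build_yield_matrix,
    classify_provenance,
    compare_extract,
    consolidate,
    coverage_curve,
    fold_change,
    group_yield,
)
from osmacnet.msio import ExtractMeta
from tests.conftest import make_spectrum


def spec(sid, mz, rt, tic, extract="e1"):
    # single peak carrying the whole TIC
    return make_spectrum(sid, precursor_mz=mz, rt=rt, peaks=[(150.0, tic)], extract_id=extract)


def meta(extract_id, strain="S01", activator="WT", media="CA02LB", clone=None):
    clone = clone or (f"{strain}_parent" if activator == "WT" else f"{strain}_{activator}_c1")
    return ExtractMeta(extract_id, strain, activator, media, clone)


class TestConsolidate:
    def test_close_spectra_merge(self):
        mets = consolidate([spec("a", 400.00, 1.0, 10.0), spec("b", 400.01, 1.1, 5.0)])
        assert len(mets) == 1
        assert sorted(mets[0].member_spectra) == ["a", "b"]
        assert mets[0].mean_precursor_mz == pytest.approx(400.005)

    def test_distant_spectra_stay_apart(self):
        mets = consolidate([spec("a", 400.0, 1.0, 10.0), spec("b", 400.5, 1.0, 5.0)])
        assert len(mets) == 2

    def test_rt_tolerance_respected(self):
        mets = consolidate([spec("a", 400.0, 1.0, 10.0), spec("b", 400.0, 1.5, 5.0)])
        assert len(mets) == 2  # 0.5 min apart > 0.4 min tolerance

    def test_greedy_chain_follows_tic_seed_order(self):
        """A~B, B~C, A!~C with TIC(A)>TIC(C)>TIC(B): hand-traced greedy result.

        A (400.000) founds M0; C (400.036) is beyond tolerance of M0 and founds
        M1; B (400.018) is within tolerance of both running means and joins the
        earliest-founded, M0.
        """
        a = spec("A", 400.000, 1.0, 300.0)
        b = spec("B", 400.018, 1.0, 100.0)
        c = spec("C", 400.036, 1.0, 200.0)
        mets = consolidate([b, c, a])
        groups = sorted(sorted(m.member_spectra) for m in mets)
        assert groups == [["A", "B"], ["C"]]

    def test_every_spectrum_assigned_exactly_once(self):
        rng = np.random.default_rng(1)
        spectra = [
            spec(f"s{i}", float(rng.uniform(400, 401)), float(rng.uniform(0, 4)), float(rng.uniform(1, 100)))
            for i in range(60)
        ]
        mets = consolidate(spectra)
        members = sorted(itertools.chain.from_iterable(m.member_spectra for m in mets))
        assert members == sorted(s.spectrum_id for s in spectra)

    def test_partition_invariant_under_input_shuffle(self):
        rng = np.random.default_rng(2)
        spectra = [
            spec(f"s{i}", float(rng.uniform(400, 400.5)), float(rng.uniform(0, 2)), float(rng.uniform(1, 100)))
            for i in range(40)
        ]
        ref = sorted(sorted(m.member_spectra) for m in consolidate(spectra))
        shuffled = list(spectra)
        rng.shuffle(shuffled)
        assert sorted(sorted(m.member_spectra) for m in consolidate(shuffled)) == ref

    def test_representative_is_highest_tic_member(self):
        mets = consolidate([spec("lo", 400.0, 1.0, 5.0), spec("hi", 400.0, 1.0, 50.0)])
        assert mets[0].representative_spectrum.spectrum_id == "hi"


class TestYieldMatrix:
    def test_max_rule_within_extract(self):
        spectra = [spec("a", 400.0, 1.0, 5e4, "e1"), spec("b", 400.0, 1.0, 8e4, "e1")]
        mets = consolidate(spectra)
        mat = build_yield_matrix(mets, spectra)
        assert mat.loc[mets[0].metabolite_id, "e1"] == 8e4

    def test_absent_metabolite_is_zero(self):
        spectra = [spec("a", 400.0, 1.0, 5e4, "e1"), spec("b", 500.0, 1.0, 8e4, "e2")]
        mets = consolidate(spectra)
        mat = build_yield_matrix(mets, spectra)
        assert (mat.values > 0).sum() == 2 and mat.shape == (2, 2)

    def test_random_instance_matches_per_cell_brute_force(self):
        rng = np.random.default_rng(4)
        spectra = []
        for i in range(120):
            mz = 400.0 + rng.integers(0, 10) * 0.5  # 10 distinct metabolites
            spectra.append(spec(f"s{i}", float(mz), 1.0, float(rng.uniform(1, 1e5)), f"e{rng.integers(6)}"))
        mets = consolidate(spectra)
        mat = build_yield_matrix(mets, spectra)
        by_id = {s.spectrum_id: s for s in spectra}
        for m in mets:
            for e in mat.columns:
                tics = [by_id[s].tic for s in m.member_spectra if by_id[s].extract_id == e]
                assert mat.loc[m.metabolite_id, e] == (max(tics) if tics else 0.0)


class TestGroupYield:
    def make_matrix(self):
        mat = pd.DataFrame(
            {"e1": [100.0], "e2": [300.0], "e3": [250.0]}, index=["M0"]
        )
        md = {
            "e1": meta("e1", "S01", "WT", "CA02LB"),
            "e2": meta("e2", "S01", "WT", "CA07LB"),
            "e3": meta("e3", "S02", "WT", "CA02LB"),
        }
        return mat, md

    def test_max_over_media_within_strain(self):
        mat, md = self.make_matrix()
        y = group_yield(mat[["e1", "e2"]], md, "wildtype")
        assert y["M0"] == 300.0

    def test_max_over_strains_within_group(self):
        mat, md = self.make_matrix()
        assert group_yield(mat, md, "wildtype")["M0"] == 300.0

    def test_empty_group_raises(self):
        mat, md = self.make_matrix()
        with pytest.raises(ValueError):
            group_yield(mat, md, "mutant")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nested_max_equals_flat_max(self, seed):
        """Max over media within strain then over strains == flat max over extracts."""
        rng = np.random.default_rng(seed)
        strains = ["S01", "S02", "S03"]
        media = ["CA02LB", "CA07LB"]
        md, cols = {}, {}
        for s in strains:
            for m in media:
                e = f"{s}_{m}"
                md[e] = meta(e, s, "WT", m)
                cols[e] = rng.uniform(0, 1e5, 5)
        mat = pd.DataFrame(cols, index=[f"M{i}" for i in range(5)])
        nested = pd.concat(
            [mat[[f"{s}_{m}" for m in media]].max(axis=1) for s in strains], axis=1
        ).max(axis=1)
        pd.testing.assert_series_equal(group_yield(mat, md, "wildtype"), nested)


class TestFoldChange:
    def test_equal_yields(self):
        assert fold_change(100.0, 100.0) == 1.0

    def test_direct_ratio(self):
        assert fold_change(4.06e5, 2.0e3) == pytest.approx(203.0)

    def test_zero_wildtype_raises(self):
        with pytest.raises(UndefinedFoldChangeError):
            fold_change(10.0, 0.0)

    def test_binning(self):
        fcs = {"a": 0.5, "b": 1.0, "c": 1.9, "d": 2.0, "e": 3.5, "f": 4.0, "g": 200.0}
        dist = bin_fold_changes(fcs)
        assert dist == {"<1": 1, "1-2": 2, "2-3": 1, "3-4": 1, ">=4": 2}


class TestProvenance:
    def build(self, wt, mu):
        """wt/mu: per-metabolite yields in a single WT / mutant extract."""
        mat = pd.DataFrame({"wt1": wt, "mu1": mu}, index=[f"M{i}" for i in range(len(wt))])
        md = {"wt1": meta("wt1"), "mu1": meta("mu1", activator="Crp")}
        return mat, md

    def test_mutant_only_is_activated_only(self):
        mat, md = self.build([0.0], [5.0])
        rep = classify_provenance(mat, md)
        assert rep.activated_only == {"M0"} and not rep.both and not rep.native_only

    def test_downregulated_shared_metabolite_lands_in_first_bin(self):
        mat, md = self.build([10.0], [5.0])
        rep = classify_provenance(mat, md)
        assert rep.both == {"M0"}
        assert rep.fold_changes["M0"] == 0.5
        assert rep.distribution["<1"] == 1

    def test_sets_partition_detected_metabolites(self):
        mat, md = self.build([1.0, 0.0, 2.0], [0.0, 3.0, 4.0])
        rep = classify_provenance(mat, md)
        assert rep.native_only == {"M0"}
        assert rep.activated_only == {"M1"}
        assert rep.both == {"M2"}
        assert rep.n_detected == 3

    def test_random_instance_matches_per_metabolite_brute_force(self):
        rng = np.random.default_rng(9)
        n = 20
        wt = np.where(rng.random(n) < 0.5, rng.uniform(1, 100, n), 0.0)
        mu = np.where(rng.random(n) < 0.5, rng.uniform(1, 100, n), 0.0)
        mat, md = self.build(list(wt), list(mu))
        rep = classify_provenance(mat, md)
        for i in range(n):
            mid = f"M{i}"
            if wt[i] > 0 and mu[i] > 0:
                assert mid in rep.both
                assert rep.fold_changes[mid] == pytest.approx(mu[i] / wt[i])
            elif wt[i] > 0:
                assert mid in rep.native_only
            elif mu[i] > 0:
                assert mid in rep.activated_only
            else:
                assert mid not in rep.both | rep.native_only | rep.activated_only

    def test_detection_threshold_variant(self):
        """The MS1-style >=1e5 detection predicate reclassifies weak signals."""
        mat, md = self.build([5e4], [5e5])
        rep = classify_provenance(mat, md, detection_threshold=1e5)
        assert rep.activated_only == {"M0"}


class TestCompareExtract:
    def build(self):
        mat = pd.DataFrame(
            {"wt": [10.0, 5.0, 0.0], "mu": [10.0, 5.0, 0.0]},
            index=["M0", "M1", "M2"],
        )
        md = {"wt": meta("wt"), "mu": meta("mu", activator="Crp")}
        return mat, md

    def test_identical_profiles_unperturbed(self):
        mat, md = self.build()
        assert compare_extract(mat, "mu", "wt", md) is False

    def test_new_metabolite_detected(self):
        mat, md = self.build()
        mat.loc["M2", "mu"] = 1.0
        assert compare_extract(mat, "mu", "wt", md) is True

    def test_upregulated_metabolite_detected(self):
        mat, md = self.build()
        mat.loc["M0", "mu"] = 10.5
        assert compare_extract(mat, "mu", "wt", md) is True

    def test_ratio_exactly_one_is_not_upregulation(self):
        mat, md = self.build()  # strict > on the yield ratio
        assert compare_extract(mat, "mu", "wt", md) is False

    def test_media_mismatch_raises(self):
        mat, md = self.build()
        md["mu"] = meta("mu", activator="Crp", media="CA07LB")
        with pytest.raises(ValueError):
            compare_extract(mat, "mu", "wt", md)


class TestCoverage:
    def test_three_media_toy_instance(self):
        curve = coverage_curve(
            {"A": {"m1", "m2"}, "B": {"m2", "m3"}, "C": {"m3", "m4"}}
        )
        mean1, sd1, n1 = curve.points[1]
        mean2, sd2, n2 = curve.points[2]
        mean3, sd3, n3 = curve.points[3]
        assert (mean1, sd1, n1) == (50.0, 0.0, 3)
        assert mean2 == pytest.approx(83.3333, abs=1e-3)
        assert sd2 == pytest.approx(11.7851, abs=1e-3)  # population SD over 3 subsets
        assert (mean3, sd3, n3) == (100.0, 0.0, 1)
        assert curve.reference_max == 4

    def test_identical_conditions_are_flat_at_100(self):
        curve = coverage_curve({c: {"m1", "m2"} for c in "ABCD"})
        for k, (mean, sd, _) in curve.points.items():
            assert mean == 100.0 and sd == 0.0

    def test_full_subset_is_exactly_100(self):
        rng = np.random.default_rng(0)
        sets = {f"c{i}": {f"m{j}" for j in rng.integers(0, 30, 10)} for i in range(5)}
        curve = coverage_curve(sets)
        assert curve.points[5][0] == 100.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_cond=st.integers(1, 6))
    def test_monotone_and_terminal(self, seed, n_cond):
        rng = np.random.default_rng(seed)
        sets = {
            f"c{i}": {f"m{j}" for j in rng.integers(0, 40, int(rng.integers(1, 15)))}
            for i in range(n_cond)
        }
        curve = coverage_curve(sets)
        means = [curve.points[k][0] for k in range(1, n_cond + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
        assert means[-1] == pytest.approx(100.0)
        assert all(curve.points[k][1] >= 0 for k in curve.points)

    def test_errors(self):
        with pytest.raises(ValueError):
            coverage_curve({})
        with pytest.raises(ValueError):
            coverage_curve({"A": set(), "B": set()})
        with pytest.raises(ValueError):
            coverage_curve({f"c{i}": {"m"} for i in range(9)})
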