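import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubscape._codes import SENSE_CODONS, SYN_FAMILIES
from cubscape.codon_metrics import (
    cai,
    classify_cub,
    ecai,
    ecai_replicate_cais,
    gc,
    gc3,
    nc,
    nc_details,
    percent_difference,
    region_report,
    reports_to_frame,
    tolerance_factor,
    _calibrate_theta,
    _tilted_family_probs,
)
from cubscape._codes import gc_count, translate_codon
from cubscape.seqio import CodingSequence, CodonUsageTable, DomainPartition, Region
from oracles import wright_nc_single_two_fold

from conftest import most_frequent_cds


def one_codon_per_family_cds(repeats: int = 10) -> list[str]:
    """Maximal bias with full coverage: a single codon for each of the 18
    degenerate amino acids plus Met and Trp."""
    codons = ["ATG", "TGG"]
    for aa, fam in SYN_FAMILIES.items():
        if aa != "*" and len(fam) >= 2:
            codons.extend([fam[0]] * repeats)
    return codons


def all_sense_codons_cds(copies: int = 100) -> list[str]:
    return [c for c in SENSE_CODONS for _ in range(copies)]


class TestNc:
    def test_maximal_bias_is_twenty(self):
        assert nc(one_codon_per_family_cds()) == 20.0

    def test_uniform_usage_truncates_to_sixtyone(self):
        result = nc_details(all_sense_codons_cds())
        assert result.value == 61.0
        assert result.truncated

    def test_phe_only_hand_value(self):
        # counts TTT=3, TTC=1: sum p^2 = 0.625, F = 0.5, Nc = 1/F = 2
        assert nc(["TTT", "TTT", "TTT", "TTC"]) == pytest.approx(2.0)

    def test_matches_two_fold_oracle(self):
        for n1 in range(0, 9):
            for n2 in range(0, 9 - n1):
                codons = ["TTT"] * n1 + ["TTC"] * n2
                expected = wright_nc_single_two_fold(n1, n2)
                assert nc(codons) == pytest.approx(expected) if expected else nc(codons) is None

    def test_concentration_never_increases_nc(self):
        # moving one count from the minority codon to the majority codon
        # (more bias) never increases Nc; exhaustive for n <= 8, k = 2
        for n in range(2, 9):
            for n1 in range(n // 2, n):
                base = wright_nc_single_two_fold(n1, n - n1)
                conc = wright_nc_single_two_fold(n1 + 1, n - n1 - 1)
                if base is not None and conc is not None:
                    assert conc <= base + 1e-12

    def test_order_invariance(self, rng):
        codons = one_codon_per_family_cds(3) + ["GGT", "GGC", "GGA"]
        shuffled = list(codons)
        rng.shuffle(shuffled)
        assert nc(shuffled) == nc(codons)

    def test_undefined_when_no_family_repeats(self):
        assert nc(["ATG", "TGG"]) is None
        assert nc(["TTT"]) is None

    def test_three_fold_substitution_rule(self):
        # Ile present once per codon (n=3, uniform) plus estimable 2- and
        # 4-fold families: F3 falls back to (F2+F4)/2 only when needed
        codons = ["ATT", "ATC", "ATA"] * 2 + ["TTT"] * 4 + ["GGG"] * 4
        value = nc(codons)
        assert value is not None
        codons_no_ile = ["TTT"] * 4 + ["GGG"] * 4
        assert nc(codons_no_ile) == pytest.approx(2.0)

    def test_ncw_variant_uses_pseudocounts(self):
        # Phe TTT=3, TTC=1: p = (4/6, 2/6), F = 20/36, Ncw = 1.8
        assert nc(["TTT", "TTT", "TTT", "TTC"], variant="ncw") == pytest.approx(1.8)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            nc(["TTT", "TTC"], variant="bogus")


class TestClassifyCub:
    @pytest.mark.parametrize(
        "value,expected",
        [(34.0, True), (35.0, True), (35.01, False), (57.0, False), (30.0, True), (44.0, False)],
    )
    def test_cutoff_boundary(self, value, expected):
        assert classify_cub(value) is expected

    def test_undefined_nc_gives_undefined_flag(self):
        assert classify_cub(None) is None


class TestCai:
    def test_most_frequent_codons_give_one(self, skewed_table):
        cds = most_frequent_cds(skewed_table, "MLKVRAGSTWPFYHQINCDE")
        assert cai(cds, skewed_table) == pytest.approx(1.0)

    def test_hand_geometric_mean(self, uniform_table):
        freqs = dict(uniform_table.freq_per_thousand)
        freqs["TTT"], freqs["TTC"] = 30.0, 10.0
        table = CodonUsageTable("x", freqs)
        assert cai(["TTT", "TTC"], table) == pytest.approx(math.sqrt(1 / 3), abs=1e-12)

    def test_order_invariance(self, skewed_table, rng):
        codons = [SYN_FAMILIES["L"][i % 6] for i in range(12)] + ["GGG", "GGA"]
        shuffled = list(codons)
        rng.shuffle(shuffled)
        assert cai(shuffled, skewed_table) == pytest.approx(cai(codons, skewed_table))

    def test_concatenation_between_parts(self, skewed_table):
        a = ["CTG", "CTA", "GGG", "GGA", "TTT"]
        b = ["CGC", "CGG", "AAA", "AAG"]
        lo, hi = sorted([cai(a, skewed_table), cai(b, skewed_table)])
        assert lo - 1e-12 <= cai(a + b, skewed_table) <= hi + 1e-12

    def test_met_trp_stop_excluded(self, skewed_table):
        with_extras = ["TTT", "TTC", "ATG", "TGG", "TAA"]
        assert cai(with_extras, skewed_table) == pytest.approx(
            cai(["TTT", "TTC"], skewed_table)
        )

    def test_error_when_nothing_contributes(self, skewed_table):
        with pytest.raises(ValueError):
            cai(["ATG", "TGG"], skewed_table)


class TestEcai:
    def test_uniform_table_gives_one(self, uniform_table):
        cds = CodingSequence(id="x", seq="ATG" + "CTGGGCAAA" * 10 + "TAA")
        assert ecai(cds, uniform_table, n_replicates=100, seed=0) == pytest.approx(1.0)

    def test_no_synonymous_freedom_propagates_cai_error(self, skewed_table):
        # Met/Trp-only proteins have no CAI-contributing codons at all
        with pytest.raises(ValueError):
            ecai(["ATG", "TGG", "ATG"], skewed_table, seed=0)

    def test_deterministic_under_seed(self, skewed_table, small_homolog_set):
        cds = small_homolog_set.sequences["sp01"]
        a = ecai(cds, skewed_table, n_replicates=100, seed=42)
        b = ecai(cds, skewed_table, n_replicates=100, seed=42)
        assert a == b

    def test_upper_bound_above_replicate_mean(self, skewed_table, small_homolog_set):
        cds = small_homolog_set.sequences["sp01"]
        reps = ecai_replicate_cais(cds, skewed_table, n_replicates=200, seed=7)
        assert ecai(cds, skewed_table, n_replicates=200, seed=7) > reps.mean()

    def test_tolerance_factor_against_large_sample_limit(self):
        # with huge n the tolerance factor approaches the population quantile
        assert tolerance_factor(10**6, 0.90, 0.90) == pytest.approx(1.2816, abs=1e-2)
        assert tolerance_factor(500, 0.90, 0.90) > 1.2816

    def test_gc_calibration_hits_target(self):
        protein = "LARGEPSTVKDNQHIYCWMF" * 5
        for target in (0.35, 0.45, 0.55):
            theta = _calibrate_theta(protein, target)
            achieved = sum(
                float(
                    _tilted_family_probs(aa, theta)
                    @ np.array([gc_count(c) for c in SYN_FAMILIES[aa]], dtype=float)
                )
                for aa in protein
            ) / (3 * len(protein))
            assert achieved == pytest.approx(target, abs=1e-5)

    def test_null_calibration_native_from_same_law(self, small_homolog_set):
        """A native drawn from the eCAI sampling law itself sits within the
        replicate CAI distribution (|z| <= 2 for >= 8/10 fixed seeds)."""
        cds = small_homolog_set.sequences["sp01"]
        table = small_homolog_set.tables["sp01"]
        codons = cds.sense_codons
        protein = "".join(translate_codon(c) for c in codons)
        gc_target = sum(gc_count(c) for c in codons) / (3 * len(codons))
        theta = _calibrate_theta(protein, gc_target)
        rng = np.random.default_rng(99)
        hits = 0
        for trial in range(10):
            native = CodingSequence(
                id="null",
                seq="".join(
                    SYN_FAMILIES[aa][rng.choice(len(SYN_FAMILIES[aa]), p=_tilted_family_probs(aa, theta))]
                    for aa in protein
                ),
            )
            reps = ecai_replicate_cais(native, table, n_replicates=300, seed=trial)
            z = (reps.mean() - cai(native, table)) / reps.std(ddof=1)
            hits += abs(z) <= 2.0
        assert hits >= 8


class TestGcMetrics:
    @pytest.mark.parametrize(
        "codons,expected",
        [
            (["GCG", "CCC"], 100.0),
            (["GCA", "CCT"], 0.0),
            (["ATG", "GAA", "GGC"], pytest.approx(200 / 3)),
        ],
    )
    def test_gc3_examples(self, codons, expected):
        assert gc3(codons) == expected

    @pytest.mark.parametrize(
        "codons,expected",
        [
            (["GCG", "CGC"], 100.0),
            (["ATG", "GAA"], pytest.approx(100 / 3)),
            (["ATA", "TAT", "GCG", "CGC"], 50.0),  # equal A/T and G/C halves
        ],
    )
    def test_gc_examples(self, codons, expected):
        assert gc(codons) == expected

    def test_stop_codon_excluded(self):
        assert gc3(["GGG", "TAA"]) == 100.0
        assert gc(["GGG", "TAA"]) == 100.0

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            gc3([])
        with pytest.raises(ValueError):
            gc([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=60))
    def test_gc3_equals_gc_of_third_positions(self, codons):
        thirds = [c[2] * 3 for c in codons]  # third bases as degenerate codons
        assert gc3(codons) == pytest.approx(gc(thirds))


class TestPercentDifference:
    @pytest.mark.parametrize("pair,expected", [((5.0, 5.0), 0.0), ((87, 100), -13.0), ((130, 100), 30.0)])
    def test_arithmetic(self, pair, expected):
        assert percent_difference(*pair) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.01, max_value=1000),
        st.floats(min_value=0.01, max_value=1000),
    )
    def test_antisymmetry_identity(self, a, b):
        # pd(a,b) * b == -pd(b,a) * a, i.e. pd(a,b) = -pd(b,a) * a/b
        lhs = percent_difference(a, b)
        rhs = -percent_difference(b, a) * a / b
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-9)

    def test_zero_reference_warns_nan(self):
        with pytest.warns(UserWarning):
            assert math.isnan(percent_difference(1.0, 0.0))


class TestRegionReport:
    @pytest.fixture()
    def reported(self, small_homolog_set):
        cds = small_homolog_set.sequences["sp02"]
        table = small_homolog_set.tables["sp02"]
        part = DomainPartition([Region("nterm", 0, 40), Region("core", 40, 160), Region("cterm", 160, 200)])
        params = {"ecai_replicates": 60, "first_n": 10}
        return region_report(cds, part, table, params=params, seed=5)

    def test_one_report_per_region_plus_whole_and_firstn(self, reported):
        assert [r.region_name for r in reported] == ["whole", "nterm", "core", "cterm", "first10"]

    def test_whole_region_normalizations_zero(self, reported):
        whole = reported[0]
        assert whole.nc_norm_pct == 0.0 and whole.gc3_norm_pct == 0.0 and whole.gc_norm_pct == 0.0

    def test_normalized_fields_recomputable(self, reported):
        whole, nterm = reported[0], reported[1]
        assert nterm.nc_norm_pct == pytest.approx(percent_difference(nterm.nc, whole.nc))
        assert nterm.gc3_norm_pct == pytest.approx(percent_difference(nterm.gc3_pct, whole.gc3_pct))

    def test_cub_flag_consistent_with_nc(self, reported):
        for r in reported:
            if r.nc is not None:
                assert r.cub_flag is (r.nc <= 35.0)

    def test_frame_columns(self, reported):
        frame = reports_to_frame(reported)
        assert list(frame["region"]) == ["whole", "nterm", "core", "cterm", "first10"]
        for col in ("nc", "cai", "ecai", "cai_vs_ecai_pct", "gc3_pct", "gc_pct"):
            assert col in frame.columns

    def test_single_region_equal_to_whole_normalizes_to_zero(self, small_homolog_set):
        cds = small_homolog_set.sequences["sp01"]
        table = small_homolog_set.tables["sp01"]
        part = DomainPartition([Region("all", 0, 200)])
        reports = region_report(cds, part, table, params={"ecai_replicates": 50, "first_n": 0}, seed=3)
        region = [r for r in reports if r.region_name == "all"][0]
        assert region.nc_norm_pct == pytest.approx(0.0, abs=1e-9)
        assert region.gc3_norm_pct == pytest.approx(0.0, abs=1e-9)
        assert region.gc_norm_pct == pytest.approx(0.0, abs=1e-9)
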