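import math
from dataclasses import replace

import numpy as np
import pytest

from causalmr import (
    LDPanel,
    SimTruth,
    apply_f_filter,
    filter_snps,
    harmonize,
    instrument_strength,
    ld_clump,
    select_instruments,
    simulate_gwas_pair,
)
from causalmr.exceptions import (
    ConfigurationError,
    EmptyInstrumentError,
    HarmonizationEmptyError,
    MissingFromPanelError,
)
from causalmr.instruments import InstrumentSet, align_alleles
from causalmr.io_summary import AssociationTable, VariantAssociation

from conftest import make_harmonized


def var(snp_id, pval=1e-9, ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3,
        chrom=None, pos=None, n=10000):
    return VariantAssociation(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                              beta=beta, se=se, pval=pval, n=n, eaf=eaf,
                              chrom=chrom, pos=pos)


def table(records, name="exposure", trait_type="continuous"):
    return AssociationTable(trait_name=name, trait_type=trait_type, records=records)


class TestInstrumentStrength:
    @pytest.mark.parametrize("beta,se,eaf,f,r2", [
        (0.1, 0.01, 0.5, 100.0, 0.005),
        (0.0, 0.02, 0.3, 0.0, 0.0),
        (0.06, 0.0102, 0.25, 34.6020761246, 0.00135),
    ])
    def test_known_values(self, beta, se, eaf, f, r2):
        got_f, got_r2 = instrument_strength(beta, se, eaf)
        assert math.isclose(got_f, f, rel_tol=1e-9)
        assert math.isclose(got_r2, r2, rel_tol=1e-9)

    def test_missing_eaf_gives_nan_r2(self):
        f, r2 = instrument_strength(0.1, 0.01, None)
        assert f == 100.0 and math.isnan(r2)

    def test_eaf_out_of_domain(self):
        with pytest.raises(ConfigurationError):
            instrument_strength(0.1, 0.01, 1.2)


class TestSelectInstruments:
    def test_threshold_is_strict_less(self):
        t = table([var("a", 1e-9), var("b", 1e-7), var("c", 1e-8)])
        kept = select_instruments(t, 5e-8)
        assert kept.snp_ids == ["a", "c"]

    def test_boundary_pval_excluded(self):
        t = table([var("a", 5e-8), var("b", 1e-9)])
        assert select_instruments(t, 5e-8).snp_ids == ["b"]

    def test_no_passer_raises(self):
        t = table([var("a", 0.5), var("b", 0.5)])
        with pytest.raises(EmptyInstrumentError, match="exposure"):
            select_instruments(t, 5e-8)

    def test_weak_instruments_excluded(self):
        weak = var("w", 1e-9, beta=0.01, se=0.01)  # F = 1
        t = table([var("a", 1e-9), weak])
        assert select_instruments(t, 5e-8, min_f=10).snp_ids == ["a"]
        deferred = select_instruments(t, 5e-8, min_f=None)
        assert deferred.snp_ids == ["a", "w"]
        assert apply_f_filter(deferred).snp_ids == ["a"]

    def test_pooled_r2_is_sum_of_per_snp(self):
        t = table([var("a", 1e-9, beta=0.1, eaf=0.5), var("b", 1e-9, beta=0.2, eaf=0.25)])
        inst = select_instruments(t, 5e-8)
        assert inst.pooled_r2 == pytest.approx(float(np.sum(inst.per_snp_r2)))
        assert inst.pooled_r2 == pytest.approx(0.005 + 2 * 0.04 * 0.25 * 0.75)

    def test_simulated_median_f_envelope(self):
        """Mean-F-target-35 simulation retains a median F in the low-to-mid
        thirties band once selection and the weak-instrument rule apply."""
        medians = []
        for seed in range(10):
            truth = SimTruth(n_instruments=100, n_exp=403_195,
                             instrument_h2=35 * 100 / 403_195,
                             effect_dispersion=0.3, seed=seed)
            exposure, _, _ = simulate_gwas_pair(truth)
            inst = select_instruments(exposure, 5e-8, min_f=10)
            medians.append(float(np.median(inst.per_snp_f)))
        assert 29 <= np.median(medians) <= 42


def panel3(r12, r13, r23):
    r2 = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    return LDPanel(snp_ids=["a", "b", "c"], r2=r2)


class TestLDClump:
    def make_set(self, pvals, chrom=None, pos=None):
        recs = [var(s, p,
                    chrom=None if chrom is None else chrom[i],
                    pos=None if pos is None else pos[i])
                for i, (s, p) in enumerate(zip("abc", pvals))]
        t = table(recs)
        return select_instruments(t, 1e-5, min_f=None)

    def test_greedy_hand_oracle(self):
        # most significant SNP a removes b (r2 0.5); c independent of both
        inst = self.make_set([1e-10, 1e-9, 1e-8])
        kept = ld_clump(inst, panel3(0.5, 0.0005, 0.0005), 0.001, 10_000)
        assert kept.snp_ids == ["a", "c"]

    def test_identity_matrix_keeps_all(self):
        inst = self.make_set([1e-10, 1e-9, 1e-8])
        kept = ld_clump(inst, panel3(0.0, 0.0, 0.0), 0.001, 10_000)
        assert kept.snp_ids == ["a", "b", "c"]

    def test_full_ld_keeps_single_most_significant(self):
        inst = self.make_set([1e-8, 1e-10, 1e-9])
        kept = ld_clump(inst, panel3(1.0, 1.0, 1.0), 0.001, 10_000)
        assert kept.snp_ids == ["b"]

    def test_window_limits_pruning(self):
        # correlated pair far apart on the same chromosome survives
        inst = self.make_set([1e-10, 1e-9, 1e-8],
                             chrom=["1", "1", "2"], pos=[1, 60_000_000, 5])
        kept = ld_clump(inst, panel3(0.9, 0.0, 0.0), 0.001, 10_000)
        assert set(kept.snp_ids) == {"a", "b", "c"}

    def test_missing_from_panel_raises(self):
        inst = self.make_set([1e-10, 1e-9, 1e-8])
        panel = LDPanel(snp_ids=["a", "b"], r2=np.eye(2))
        with pytest.raises(MissingFromPanelError, match="c"):
            ld_clump(inst, panel, 0.001, 10_000)

    def test_kept_pairs_below_threshold(self):
        """Clumped output is LD-independent at the threshold."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            k = 8
            a = rng.uniform(0, 1, size=(k, k))
            r2 = (a + a.T) / 2
            np.fill_diagonal(r2, 1.0)
            ids = [f"s{i}" for i in range(k)]
            recs = [var(s, p) for s, p in zip(ids, rng.uniform(1e-12, 1e-6, k))]
            inst = select_instruments(table(recs), 1e-3, min_f=None)
            panel = LDPanel(snp_ids=ids, r2=r2)
            kept = ld_clump(inst, panel, 0.3, 10_000)
            for i, a_id in enumerate(kept.snp_ids):
                for b_id in kept.snp_ids[i + 1:]:
                    assert panel.r2_between(a_id, b_id) < 0.3


def outcome_table(records, name="outcome"):
    return AssociationTable(trait_name=name, trait_type="binary", records=records)


def inst_set(records):
    t = table(records)
    return select_instruments(t, 1e-5, min_f=None)


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        inst = inst_set([var("rs1", ea="A", oa="G")])
        out = outcome_table([var("rs1", ea="G", oa="A", beta=0.2, eaf=0.7)])
        h = harmonize(inst, out)
        assert h.by[0] == pytest.approx(-0.2)
        assert h.eaf_y[0] == pytest.approx(0.3)

    def test_palindromic_ambiguous_dropped(self):
        inst = inst_set([var("rs1", ea="A", oa="T", eaf=0.50), var("rs2")])
        out = outcome_table([var("rs1", ea="A", oa="T", eaf=0.50), var("rs2")])
        h = harmonize(inst, out)
        assert ("rs1", "palindromic_ambiguous") in h.dropped
        assert h.snp_ids == ["rs2"]

    def test_palindromic_resolved_by_frequency(self):
        inst = inst_set([var("rs1", ea="A", oa="T", eaf=0.10)])
        out = outcome_table([var("rs1", ea="A", oa="T", beta=0.2, eaf=0.88)])
        h = harmonize(inst, out)  # frequencies disagree -> swap orientation
        assert h.by[0] == pytest.approx(-0.2)

    def test_eight_orientation_cases(self):
        """Truth table of allele orientations against exposure A/G."""
        cases = [  # (outcome EA, OA, expected alignment)
            ("A", "G", "same"), ("G", "A", "swap"),
            ("T", "C", "same"), ("C", "T", "swap"),
            ("A", "C", None), ("C", "A", None),
            ("T", "G", None), ("G", "T", None),
        ]
        for ea, oa, want in cases:
            assert align_alleles("A", "G", ea, oa) == want, (ea, oa)

    def test_strand_flip_keeps_sign(self):
        inst = inst_set([var("rs1", ea="A", oa="G", eaf=0.3)])
        out = outcome_table([var("rs1", ea="T", oa="C", beta=0.2, eaf=0.3)])
        h = harmonize(inst, out)
        assert h.by[0] == pytest.approx(0.2)

    def test_missing_and_mismatch_reasons(self):
        inst = inst_set([var("rs1"), var("rs2", ea="A", oa="G"), var("rs3")])
        out = outcome_table([var("rs2", ea="A", oa="C"), var("rs3")])
        h = harmonize(inst, out)
        assert ("rs1", "missing_in_outcome") in h.dropped
        assert ("rs2", "allele_mismatch") in h.dropped
        assert h.snp_ids == ["rs3"]

    def test_proxy_substitution(self):
        inst = inst_set([var("rs1", ea="A", oa="G", beta=0.15)])
        out = outcome_table([var("rsP", ea="A", oa="G", beta=0.07)])
        panel = LDPanel(snp_ids=["rs1", "rsP"], r2=np.eye(2),
                        proxy_table=[("rs1", "rsP", 0.95)])
        h = harmonize(inst, out, panel=panel)
        assert h.snp_ids == ["rs1"]
        assert h.bx[0] == pytest.approx(0.15)  # exposure effect kept
        assert h.by[0] == pytest.approx(0.07)  # outcome row from the proxy

    def test_empty_survivors_raise(self):
        inst = inst_set([var("rs1")])
        out = outcome_table([var("rsX")])
        with pytest.raises(HarmonizationEmptyError):
            harmonize(inst, out)

    def test_idempotent_on_aligned_data(self):
        truth = SimTruth(n_instruments=20, seed=3)
        exposure, outcome, _ = simulate_gwas_pair(truth)
        inst = select_instruments(exposure, 5e-8, min_f=None)
        h1 = harmonize(inst, outcome)
        h2 = harmonize(inst, outcome)
        np.testing.assert_array_equal(h1.by, h2.by)
        assert h1.snp_ids == h2.snp_ids
        assert not [d for d in h1.dropped if d[1] == "allele_mismatch"]


class TestFilterSnps:
    def test_empty_exclusion_is_identity(self, toy_b):
        h = filter_snps(toy_b, [], "none")
        assert h.snp_ids == toy_b.snp_ids
        np.testing.assert_array_equal(h.by, toy_b.by)

    def test_single_exclusion(self, toy_b):
        h = filter_snps(toy_b, ["rs1"], "pleiotropic")
        assert h.nsnp == 2
        assert ("rs1", "pleiotropic") in h.dropped

    def test_pleiotropic_list_arithmetic(self):
        h = make_harmonized(np.full(121, 0.1), np.full(121, 0.05),
                            snp_ids=[f"v{i}" for i in range(121)])
        kept = filter_snps(h, [f"v{i}" for i in range(46)], "pleiotropic")
        assert kept.nsnp == 75

    def test_exhausting_exclusion_raises(self, toy_b):
        with pytest.raises(HarmonizationEmptyError):
            filter_snps(toy_b, list(toy_b.snp_ids), "all")
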