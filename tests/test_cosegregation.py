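"""Dominant-model filter cascade: oracles, policies and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haph.cosegregation import (
    FilterConfig,
    carrier_vector,
    class_filter,
    collapse_cis,
    default_stages,
    dominant_filter,
    run_cascade,
)
from haph.io_formats import GenotypeMatrix, VariantRecord


def _matrix_from_codes(codes: np.ndarray, genes=None) -> GenotypeMatrix:
    n_var, n_samp = codes.shape
    samples = [f"S{i}" for i in range(n_samp)]
    genes = genes or [f"G{i}" for i in range(n_var)]
    records = [
        VariantRecord("1", 100 + i, "A", "G", codes[i], gene=genes[i],
                      var_class="nonsynonymous SNV")
        for i in range(n_var)
    ]
    return GenotypeMatrix(samples=samples, records=records)


def _status(n_aff: int, n_unaff: int) -> dict:
    status = {f"S{i}": "affected" for i in range(n_aff)}
    status.update({f"S{i}": "unaffected" for i in range(n_aff, n_aff + n_unaff)})
    return status


class TestCarrierVector:
    def test_dominant_semantics(self):
        rec = VariantRecord("1", 1, "A", "G", np.array([0, 1, 2, -1]))
        assert list(carrier_vector(rec)) == [False, True, True, False]

    def test_missing_as_noncarrier(self):
        rec = VariantRecord("1", 1, "A", "G", np.array([-1, -1]))
        assert not carrier_vector(rec, "as_noncarrier").any()


class TestClassFilter:
    def _rec(self, var_class):
        return VariantRecord("1", 1, "A", "G", np.array([1]), gene="X",
                             var_class=var_class)

    def test_synonymous_removed_indel_kept(self):
        recs = [self._rec("synonymous SNV"), self._rec("frameshift insertion"),
                self._rec("nonsynonymous SNV")]
        kept = class_filter(recs)
        assert [r.var_class for r in kept] == ["frameshift insertion", "nonsynonymous SNV"]

    def test_empty_class_set(self):
        assert class_filter([self._rec("nonsynonymous SNV")], classes=set()) == []

    def test_unannotated_drop_vs_keep(self, caplog):
        recs = [self._rec("")]
        with caplog.at_level("WARNING"):
            assert class_filter(recs) == []
        assert class_filter(recs, keep_unannotated=True) == recs


class TestDominantFilter:
    def test_paper_stage_5v5(self):
        # carrier in 5/5 affected, 0/5 unaffected passes (>=4, <=0)
        codes = np.array([[1] * 5 + [0] * 5])
        m = _matrix_from_codes(codes)
        cfg = FilterConfig(4, 0, 5, 5)
        assert len(dominant_filter(m, _status(5, 5), cfg)) == 1

    def test_ubiquitous_variant_fails(self):
        codes = np.array([[1] * 10])
        m = _matrix_from_codes(codes)
        for max_u in range(5):
            cfg = FilterConfig(0, max_u, 5, 5)
            assert dominant_filter(m, _status(5, 5), cfg) == []

    def test_missing_status_is_error(self):
        m = _matrix_from_codes(np.array([[1, 0]]))
        with pytest.raises(ValueError, match="no status"):
            dominant_filter(m, {"S0": "affected"}, FilterConfig(1, 0, 1, 1))

    def test_indeterminate_status_is_error(self):
        m = _matrix_from_codes(np.array([[1, 0]]))
        with pytest.raises(ValueError, match="indeterminate"):
            dominant_filter(
                m, {"S0": "affected", "S1": "indeterminate"}, FilterConfig(1, 0, 1, 1)
            )

    def test_missing_policy_as_fail(self):
        codes = np.array([[1, 1, 1, 1, -1] + [0] * 5])
        m = _matrix_from_codes(codes)
        lenient = FilterConfig(4, 0, 5, 5, missing_policy="as_noncarrier")
        strict = FilterConfig(4, 0, 5, 5, missing_policy="as_fail")
        assert len(dominant_filter(m, _status(5, 5), lenient)) == 1
        assert dominant_filter(m, _status(5, 5), strict) == []

    def test_pre_mask_turns_calls_missing(self):
        codes = np.array([[1] * 5 + [0] * 5])
        m = _matrix_from_codes(codes)
        mask = np.zeros_like(codes, dtype=bool)
        mask[0, 0] = True  # GQ failure on one affected carrier call
        cfg = FilterConfig(5, 0, 5, 5)
        assert len(dominant_filter(m, _status(5, 5), cfg)) == 1
        assert dominant_filter(m, _status(5, 5), cfg, pre_mask=mask) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.choice([-1, 0, 1, 2], size=(200, 10), p=[0.05, 0.6, 0.25, 0.1]).astype(np.int8)
        m = _matrix_from_codes(codes)
        status = _status(5, 5)
        cfg = FilterConfig(
            int(rng.integers(0, 6)), int(rng.integers(0, 6)), 5, 5
        )
        got = {r.variant_id for r in dominant_filter(m, status, cfg)}
        expect = set()
        for rec in m.records:
            aff = sum(1 for i in range(5) if rec.genotypes[i] in (1, 2))
            unaff = sum(1 for i in range(5, 10) if rec.genotypes[i] in (1, 2))
            if aff >= cfg.min_affected_carriers and unaff <= cfg.max_unaffected_carriers:
                expect.add(rec.variant_id)
        assert got == expect

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        data=st.data(),
        lo=st.integers(0, 5),
        hi=st.integers(0, 5),
    )
    def test_threshold_monotonicity(self, data, lo, hi):
        """Relaxing either threshold never removes a passing variant."""
        codes = np.array(
            data.draw(
                st.lists(
                    st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=10, max_size=10),
                    min_size=1,
                    max_size=20,
                )
            ),
            dtype=np.int8,
        )
        m = _matrix_from_codes(codes)
        status = _status(5, 5)
        base = {r.variant_id for r in dominant_filter(m, status, FilterConfig(lo, hi, 5, 5))}
        if lo > 0:
            relaxed = {r.variant_id for r in dominant_filter(m, status, FilterConfig(lo - 1, hi, 5, 5))}
            assert base <= relaxed
        if hi < 5:
            relaxed = {r.variant_id for r in dominant_filter(m, status, FilterConfig(lo, hi + 1, 5, 5))}
            assert base <= relaxed


class TestCollapseCis:
    def test_identical_carriers_one_unit(self, small_matrix):
        units = collapse_cis(small_matrix.records[:2])
        assert len(units) == 1
        assert units[0].n_members == 2
        assert units[0].gene == "GENEA"

    def test_differing_carrier_sets_stay_apart(self):
        recs = [
            VariantRecord("1", 1, "A", "G", np.array([1, 1, 0]), gene="X"),
            VariantRecord("1", 2, "A", "G", np.array([1, 0, 0]), gene="X"),
        ]
        assert len(collapse_cis(recs)) == 2

    def test_same_carriers_different_genes_stay_apart(self):
        recs = [
            VariantRecord("1", 1, "A", "G", np.array([1, 0]), gene="X"),
            VariantRecord("2", 1, "A", "G", np.array([1, 0]), gene="Y"),
        ]
        assert len(collapse_cis(recs)) == 2

    def test_idempotent(self, small_matrix):
        once = collapse_cis(small_matrix.records)
        again = collapse_cis([m for u in once for m in u.members])
        assert len(once) == len(again)
        assert {u.carrier_mask.tobytes() for u in once} == {
            u.carrier_mask.tobytes() for u in again
        }


class TestCascade:
    def test_planted_haplotype_passes_strictest_stage(self):
        codes = np.vstack(
            [
                [1] * 5 + [0] * 5,  # causal pair, penetrance 1
                [1] * 5 + [0] * 5,
                np.random.default_rng(0).choice([0, 1], 10),
            ]
        ).astype(np.int8)
        m = _matrix_from_codes(codes, genes=["CAUSAL", "CAUSAL", "BG"])
        rep = run_cascade(m, _status(5, 5), default_stages(5, 5))
        strictest = rep.stages[0]
        assert strictest.config.label == "(5,0)"
        assert "CAUSAL" in strictest.genes
        unit = [u for u in strictest.units if u.gene == "CAUSAL"][0]
        assert unit.n_members == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_stage_nesting(self, seed):
        """Gene sets obey S(5,0) <= S(4,0) <= S(4,1)."""
        rng = np.random.default_rng(seed)
        codes = rng.choice([0, 1], size=(300, 10), p=[0.7, 0.3]).astype(np.int8)
        m = _matrix_from_codes(codes)
        rep = run_cascade(m, _status(5, 5), default_stages(5, 5))
        g50, g41, g40 = (set(s.genes) for s in rep.stages)
        assert g50 <= g40 <= g41

    def test_counts_match_independent_recount(self, demo_cohort):
        rep = run_cascade(
            demo_cohort.matrix, demo_cohort.status, default_stages(5, 5)
        )
        for stage in rep.stages:
            cfg = stage.config
            n_pass = 0
            genes = set()
            for rec in demo_cohort.matrix.records:
                if rec.var_class != "nonsynonymous SNV":
                    continue
                aff = sum(
                    1
                    for s, g in zip(demo_cohort.matrix.samples, rec.genotypes)
                    if demo_cohort.status[s] == "affected" and g in (1, 2)
                )
                unaff = sum(
                    1
                    for s, g in zip(demo_cohort.matrix.samples, rec.genotypes)
                    if demo_cohort.status[s] == "unaffected" and g in (1, 2)
                )
                if aff >= cfg.min_affected_carriers and unaff <= cfg.max_unaffected_carriers:
                    n_pass += 1
                    genes.add(rec.gene)
            assert stage.n_variants == n_pass
            assert stage.n_genes == len(genes)
            # structural count ordering
            assert stage.n_genes <= len(stage.units) <= stage.n_variants or n_pass == 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(6, 0, 5, 5)
        with pytest.raises(ValueError):
            FilterConfig(4, 6, 5, 5)
        with pytest.raises(ValueError):
            FilterConfig(4, 0, 5, 5, missing_policy="imputed")
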