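"""Tandem copy counting, comparative-Ct quantification, locus dissection."""

import numpy as np
import pandas as pd
import pytest

from strainkit import (
    Assembly,
    count_tandem_copies,
    ddct_fold,
    infer_calibrator_copies,
    locus_gene_structure,
    make_tandem_array,
)
from strainkit.simulate import random_sequence, random_te_library

MARKER = random_te_library(1, 500, seed=41)["TY1"]


def _cq_table(rows):
    return pd.DataFrame(
        rows, columns=["sample", "target", "reference", "replicate",
                       "cq_target", "cq_reference"]
    )


def _flat_table(samples, cq_ref=20.0, target="CUP1"):
    rows = []
    for sample, cq_t in samples.items():
        for rep in range(3):
            rows.append((sample, target, "ACT1", rep, cq_t, cq_ref))
    return _cq_table(rows)


class TestCountTandemCopies:
    @pytest.mark.parametrize("n", [0, 1, 2, 8, 16])
    def test_constructed_copy_number_recovered(self, n):
        asm = make_tandem_array(MARKER, n, 400, seed=n, divergence=0.03)
        assert count_tandem_copies(asm, MARKER) == n

    def test_marker_absent_gives_zero(self, rng):
        asm = Assembly()
        asm.add("c", random_sequence(20_000, rng))
        assert count_tandem_copies(asm, MARKER) == 0

    def test_invariant_under_reverse_complement(self):
        asm = make_tandem_array(MARKER, 8, 400, seed=3, divergence=0.02)
        assert count_tandem_copies(asm.reverse_complement(), MARKER) == 8

    def test_empty_marker_rejected(self):
        with pytest.raises(ValueError):
            count_tandem_copies(Assembly(), "")


class TestDdctFold:
    def test_equal_means_give_unit_fold(self):
        tab = _flat_table({"cal": 20.0, "s": 20.0})
        assert ddct_fold(tab, "s", "cal", "CUP1").fold == pytest.approx(1.0)

    def test_sample_equals_calibrator_is_exactly_one(self):
        rng = np.random.default_rng(0)
        rows = [("cal", "CUP1", "ACT1", i, 20 + rng.normal(0, 0.3),
                 19 + rng.normal(0, 0.3)) for i in range(3)]
        res = ddct_fold(_cq_table(rows), "cal", "cal", "CUP1")
        assert res.fold == 1.0
        assert res.ddct == 0.0

    @pytest.mark.parametrize("delta,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
    def test_closed_forms(self, delta, expected):
        tab = _flat_table({"cal": 20.0, "s": 20.0 + delta})
        assert ddct_fold(tab, "s", "cal", "CUP1").fold == pytest.approx(expected)

    def test_missing_sample_rows_reported(self):
        tab = _flat_table({"cal": 20.0})
        with pytest.raises(ValueError, match="ghost"):
            ddct_fold(tab, "ghost", "cal", "CUP1")

    def test_replicate_noise_propagates_to_sd(self):
        rng = np.random.default_rng(5)
        rows = []
        for s, cq in [("cal", 20.0), ("s", 21.0)]:
            for rep in range(3):
                rows.append((s, "CUP1", "ACT1", rep,
                             cq + rng.normal(0, 0.2), 20 + rng.normal(0, 0.2)))
        res = ddct_fold(_cq_table(rows), "s", "cal", "CUP1")
        assert res.sd_ddct > 0
        assert res.fold_low < res.fold < res.fold_high

    def test_nonpositive_cq_rejected(self):
        tab = _flat_table({"cal": 20.0, "s": -1.0})
        with pytest.raises(ValueError, match="finite"):
            ddct_fold(tab, "s", "cal", "CUP1")


class TestInferCalibratorCopies:
    def test_half_fold_doubles_copies(self):
        assert infer_calibrator_copies(8, 0.5).inferred_calibrator_copies == 16

    def test_unit_fold_preserves_copies(self):
        assert infer_calibrator_copies(8, 1.0).inferred_calibrator_copies == 8

    def test_threefold_reduces(self):
        assert infer_calibrator_copies(3, 3.0).inferred_calibrator_copies == 1

    @pytest.mark.parametrize("fold", [0.0, -1.0])
    def test_nonpositive_fold_rejected(self, fold):
        with pytest.raises(ValueError):
            infer_calibrator_copies(8, fold)


def test_end_to_end_copy_recovery_under_cq_noise():
    """Assembly count + noisy ddCt recovers the calibrator copy number
    within 25%: sample carries 8 copies, calibrator 16, Cq noise sd 0.2,
    triplicate reactions, folds averaged over 6 biological replicates."""
    sample_copies, calibrator_copies = 8, 16
    asm = make_tandem_array(MARKER, sample_copies, 400, seed=10, divergence=0.01)
    counted = count_tandem_copies(asm, MARKER)
    assert counted == sample_copies

    rng = np.random.default_rng(17)
    folds = []
    for _ in range(6):
        rows = []
        for strain, copies in [("cal", calibrator_copies), ("s", sample_copies)]:
            for rep in range(3):
                cq_t = 20.0 - np.log2(copies) + rng.normal(0, 0.2)
                cq_r = 18.0 + rng.normal(0, 0.2)
                rows.append((strain, "CUP1", "ACT1", rep, cq_t, cq_r))
        folds.append(ddct_fold(_cq_table(rows), "s", "cal", "CUP1").fold)
    est = infer_calibrator_copies(counted, float(np.mean(folds)))
    rel_err = abs(est.inferred_calibrator_copies - calibrator_copies) / calibrator_copies
    assert rel_err <= 0.25


class TestLocusGeneStructure:
    def _mut(self, s, pos):
        table = {"A": "C", "C": "G", "G": "T", "T": "A"}
        arr = list(s)
        for p in pos:
            arr[p] = table[arr[p]]
        return "".join(arr)

    def _build(self, genes, spacer_seed=2):
        rng = np.random.default_rng(spacer_seed)
        parts = [random_sequence(400, rng)]
        for g in genes:
            parts.append(g)
            parts.append(random_sequence(400, rng))
        asm = Assembly()
        asm.add("locus", "".join(parts))
        return asm

    def test_tandem_paralogs_ordered_with_planted_substitution_counts(self):
        rng = np.random.default_rng(43)
        A, B, C = (random_sequence(900, rng) for _ in range(3))
        B1 = self._mut(B, [100])
        B2 = self._mut(B, [200, 300])
        asm = self._build([A, B, B1, B2, C])
        ls = locus_gene_structure(asm, {"geneA": A, "geneB": B, "geneC": C})
        assert ls.labels == ["geneA", "geneB-1", "geneB-2", "geneB-3", "geneC"]
        idx = {lab: i for i, lab in enumerate(ls.labels)}
        assert ls.substitutions[idx["geneB-1"], idx["geneB-2"]] == 1
        assert ls.substitutions[idx["geneB-1"], idx["geneB-3"]] == 2
        assert ls.substitutions[idx["geneB-2"], idx["geneB-3"]] == 3

    def test_single_exact_copy_has_empty_matrix(self):
        rng = np.random.default_rng(44)
        A = random_sequence(800, rng)
        asm = self._build([A])
        ls = locus_gene_structure(asm, {"geneA": A})
        assert ls.labels == ["geneA"]
        assert ls.copies[0].identity == 1.0
        assert ls.substitutions.shape == (1, 1)

    def test_copies_sharing_derived_mutation_cluster(self):
        """Two duplicates sharing an extra mutation have the smallest
        pairwise count, identifying the second duplication event."""
        rng = np.random.default_rng(45)
        B = random_sequence(900, rng)
        ancestral = self._mut(B, [50])          # its own single substitution
        dup1 = self._mut(B, [400, 700])         # shared (400) + private (700)
        dup2 = self._mut(B, [400, 800])         # shared (400) + private (800)
        asm = self._build([dup1, dup2, ancestral])
        ls = locus_gene_structure(asm, {"geneB": B})
        s = ls.substitutions
        pairs = {
            (i, j): s[i, j]
            for i in range(3) for j in range(i + 1, 3)
        }
        assert min(pairs, key=pairs.get) == (0, 1)  # the two duplicates
        assert pairs[(0, 1)] == 2  # private mutations only
        assert pairs[(0, 2)] == 3 and pairs[(1, 2)] == 3

    def test_empty_queries_rejected(self):
        with pytest.raises(ValueError):
            locus_gene_structure(Assembly(), {})

    def test_region_restriction(self):
        rng = np.random.default_rng(46)
        A = random_sequence(800, rng)
        asm = self._build([A, A])
        full = locus_gene_structure(asm, {"geneA": A})
        assert len(full.copies) == 2
        first = locus_gene_structure(asm, {"geneA": A}, region=("locus", 0, 1400))
        assert len(first.copies) == 1
        assert first.copies[0].start == full.copies[0].start
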