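"""Unit and property tests for the VCF -> patient-matrix chain."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vcfhir import variant_matrix as vm
from vcfhir.variant_matrix import (
    CallTable,
    SampleCall,
    Site,
    VariantRecord,
    apply_edit,
)


# ---------------------------------------------------------------------------
# read_vcf
# ---------------------------------------------------------------------------

class TestReadVcf:
    def test_maps_vcf_fields(self, write_vcf):
        path = write_vcf(["chr1\t100\t.\tA\tG\t50\tPASS\tAF=0.2\tGT:DP:PL\t0/1:30:40,0,40"])
        (rec,) = vm.read_vcf(path)
        assert (rec.chrom, rec.pos, rec.ref, rec.alts) == ("chr1", 100, "A", ["G"])
        assert rec.af == pytest.approx([0.2])
        call = rec.calls["S1"]
        assert call.gt == (0, 1) and call.dp == 30 and call.pl == (40, 0, 40)
        assert not call.imputed

    def test_missing_genotype_stays_missing(self, write_vcf):
        path = write_vcf(["chr1\t100\t.\tA\tG\t50\tPASS\tAF=0.2\tGT:DP:PL\t./.:.:."])
        (rec,) = vm.read_vcf(path)
        call = rec.calls["S1"]
        assert call.is_missing and call.dp is None and call.pl is None
        assert not call.imputed

    def test_empty_vcf_gives_empty_list(self, write_vcf):
        assert vm.read_vcf(write_vcf([])) == []

    def test_malformed_header_raises(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a VCF\n")
        with pytest.raises(vm.VcfParseError):
            vm.read_vcf(bad)

    def test_invalid_position_names_line(self, write_vcf):
        path = write_vcf(["chr1\t0\t.\tA\tG\t50\tPASS\tAF=0.2\tGT\t0/1"])
        with pytest.raises(vm.VcfParseError, match=r"line \d+"):
            vm.read_vcf(path)


# ---------------------------------------------------------------------------
# split_multiallelic
# ---------------------------------------------------------------------------

def _rec(alts, gt, af=None):
    return VariantRecord(
        "chr1", 100, "A", list(alts), af=af, calls={"S1": SampleCall(gt=gt)}
    )


class TestSplitMultiallelic:
    def test_biallelic_identity(self):
        rec = _rec(["G"], (0, 1), af=[0.2])
        assert vm.split_multiallelic(rec) == [rec]

    def test_two_alts_het_recode(self):
        out = vm.split_multiallelic(_rec(["G", "T"], (1, 2), af=[0.1, 0.3]))
        assert [r.alts for r in out] == [["G"], ["T"]]
        assert [r.af for r in out] == [[0.1], [0.3]]
        assert out[0].calls["S1"].gt == (1, 0)
        assert out[1].calls["S1"].gt == (0, 1)

    def test_hom_ref_unchanged_in_both(self):
        out = vm.split_multiallelic(_rec(["G", "T"], (0, 0)))
        assert all(r.calls["S1"].gt == (0, 0) for r in out)

    @given(
        n_alts=st.integers(2, 4),
        gt=st.tuples(st.integers(0, 4), st.integers(0, 4)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conserves_alt_allele_count(self, n_alts, gt):
        """The recode moves each alt allele to exactly one output record."""
        gt = tuple(min(a, n_alts) for a in gt)
        alts = ["G", "T", "C", "N"][:n_alts]
        out = vm.split_multiallelic(_rec(alts, gt))
        assert len(out) == n_alts
        total = sum(r.calls["S1"].dosage for r in out)
        assert total == sum(1 for a in gt if a >= 1)


# ---------------------------------------------------------------------------
# normalize
# ---------------------------------------------------------------------------

class TestNormalize:
    REF = {"chr1": "CTTTTC"}

    def test_snp_unchanged(self):
        rec = VariantRecord("chr1", 2, "T", ["G"])
        assert vm.normalize(rec, self.REF) is rec

    def test_deletion_left_aligned(self):
        rec = VariantRecord("chr1", 4, "TT", ["T"])
        out = vm.normalize(rec, self.REF)
        assert (out.pos, out.ref, out.alts) == (1, "CT", ["C"])

    def test_idempotent(self):
        out = vm.normalize(VariantRecord("chr1", 4, "TT", ["T"]), self.REF)
        again = vm.normalize(out, self.REF)
        assert (again.pos, again.ref, again.alts) == (out.pos, out.ref, out.alts)

    def test_ref_mismatch_raises(self):
        with pytest.raises(vm.ReferenceMismatchError):
            vm.normalize(VariantRecord("chr1", 2, "A", ["G"]), self.REF)

    def test_without_reference_trims_parsimoniously(self):
        out = vm.normalize(VariantRecord("chr1", 4, "TT", ["T"]), None)
        # no left shift possible without sequence context
        assert (out.pos, out.ref, out.alts) == (4, "TT", ["T"])

    @given(data=st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_random_indels_edit_equivalent_and_idempotent(self, data):
        """Normalization preserves the edited sequence and is a fixpoint."""
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rng_seed)
        # repeat-rich contig with a distinct anchor base at the start
        units = ["T", "TA", "CTT", "A"]
        seq = "G" + "".join(
            units[rng.integers(len(units))] for _ in range(rng.integers(5, 15))
        )
        pos = int(rng.integers(2, max(3, len(seq) - 4)))
        ref_len = int(rng.integers(1, 4))
        ref = seq[pos - 1 : pos - 1 + ref_len]
        alt = "".join("ACGT"[rng.integers(4)] for _ in range(rng.integers(1, 4)))
        if ref == alt or not ref:
            return
        rec = VariantRecord("chr1", pos, ref, [alt])
        out = vm.normalize(rec, {"chr1": seq})
        assert apply_edit(seq, out.pos, out.ref, out.alts[0]) == apply_edit(
            seq, pos, ref, alt
        )
        again = vm.normalize(out, {"chr1": seq})
        assert (again.pos, again.ref, again.alts) == (out.pos, out.ref, out.alts)


# ---------------------------------------------------------------------------
# ld_prune
# ---------------------------------------------------------------------------

def brute_r2(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    ca, cb = a - a.mean(), b - b.mean()
    r = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
    return r * r


class TestLdPrune:
    def test_identical_vectors_prune_second(self):
        X = np.array([[0, 1, 2, 0], [0, 1, 2, 0], [2, 0, 1, 1]])
        assert vm.ld_prune(X, 0.5, window=3, step=1) == [0, 2]

    def test_perfect_anticorrelation_pruned(self):
        X = np.array([[0, 0, 1, 1, 2, 2], [2, 2, 1, 1, 0, 0]])
        assert vm.ld_prune(X, 0.99, window=2, step=1) == [0]

    def test_threshold_decides_retention(self):
        a, b = [0, 1, 2, 0], [0, 1, 0, 1]
        r2 = brute_r2(a, b)
        X = np.array([a, b])
        kept_tight = vm.ld_prune(X, r2_threshold=r2 + 1e-6, window=2, step=1)
        kept_loose = vm.ld_prune(X, r2_threshold=r2, window=2, step=1)
        assert kept_tight == [0, 1]
        assert kept_loose == [0]

    def test_zero_variance_vector_retained(self):
        X = np.array([[1, 1, 1, 1], [0, 1, 2, 0]])
        assert vm.ld_prune(X, 0.1, window=2, step=1) == [0, 1]

    def test_chromosome_boundary_blocks_comparison(self):
        X = np.array([[0, 1, 2, 0], [0, 1, 2, 0]])
        kept = vm.ld_prune(X, 0.5, window=2, step=1, chroms=["chr1", "chr2"])
        assert kept == [0, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_retained_pairs_below_threshold_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 3, size=(25, 12)).astype(float)
        thr = 0.4
        window = 25  # single window: every retained pair must satisfy the bound
        kept = vm.ld_prune(X, thr, window=window, step=5)
        for ai, a in enumerate(kept):
            for b in kept[ai + 1 :]:
                assert brute_r2(X[a], X[b]) < thr
        assert vm.ld_prune(X, thr, window=window, step=5) == kept  # deterministic


# ---------------------------------------------------------------------------
# merge_samples / impute_missing
# ---------------------------------------------------------------------------

def _patient_records(patient, sites, gts):
    recs = []
    for (chrom, pos, ref, alt, af), gt in zip(sites, gts):
        if gt is None:
            continue
        recs.append(
            VariantRecord(
                chrom, pos, ref, [alt], af=[af],
                calls={patient: SampleCall(gt=gt, dp=30, pl=(0, 40, 80) if gt == (0, 0) else (40, 0, 40))},
            )
        )
    return recs


S1 = ("chr1", 100, "A", "G", 0.2)
S2 = ("chr1", 200, "C", "T", 0.4)
S3 = ("chr2", 50, "G", "A", 0.1)


class TestMergeSamples:
    def test_shared_sites_no_missing(self):
        t = vm.merge_samples(
            [
                _patient_records("P1", [S1, S2], [(0, 1), (0, 0)]),
                _patient_records("P2", [S1, S2], [(1, 1), (0, 1)]),
            ]
        )
        assert len(t.sites) == 2 and t.patients == ["P1", "P2"]
        assert t.missing_count() == 0

    def test_disjoint_sites_all_cross_missing(self):
        t = vm.merge_samples(
            [
                _patient_records("P1", [S1], [(0, 1)]),
                _patient_records("P2", [S2], [(0, 1)]),
            ]
        )
        assert len(t.sites) == 2 and t.missing_count() == 2

    def test_missing_count_identity(self):
        """missing = sites x patients - total calls, for partial overlap."""
        layouts = [[(0, 1), (0, 0), None], [(0, 1), None, (1, 1)], [None, (0, 1), (0, 1)]]
        t = vm.merge_samples(
            [
                _patient_records(f"P{i}", [S1, S2, S3], gts)
                for i, gts in enumerate(layouts)
            ]
        )
        total_calls = sum(1 for gts in layouts for g in gts if g is not None)
        assert t.missing_count() == len(t.sites) * len(t.patients) - total_calls

    def test_duplicate_patient_raises(self):
        recs = _patient_records("P1", [S1], [(0, 1)])
        with pytest.raises(vm.DuplicateSampleError):
            vm.merge_samples([recs, recs])

    def test_sites_ordered_by_chrom_then_pos(self):
        t = vm.merge_samples(
            [_patient_records("P1", [S3, S2, S1], [(0, 1), (0, 1), (0, 1)])]
        )
        assert [(s.chrom, s.pos) for s in t.sites] == [
            ("chr1", 100), ("chr1", 200), ("chr2", 50),
        ]


def _table_with_missing():
    """P1 called at two sites (DP 20/30, GQ 40/60), missing at the third."""
    sites = [Site("chr1", 100, "A", "G", 0.2), Site("chr1", 200, "C", "T", 0.4),
             Site("chr1", 300, "G", "A", 0.1)]
    calls = [
        {"P1": SampleCall((0, 1), dp=20, pl=(40, 0, 90))},
        {"P1": SampleCall((0, 0), dp=30, pl=(0, 60, 120))},
        {"P1": SampleCall(None)},
    ]
    return CallTable(sites=sites, patients=["P1"], calls=calls)


class TestImputeMissing:
    def test_imputed_call_uses_patient_means(self):
        out = vm.impute_missing(_table_with_missing())
        call = out.calls[2]["P1"]
        assert call.gt == (0, 0)
        assert call.dp == 25  # round(mean(20, 30))
        assert call.pl == (0, 50, 100)  # g = round(mean GQ(40, 60)) = 50
        assert call.imputed

    def test_no_missing_is_identity(self):
        t = vm.merge_samples(
            [_patient_records("P1", [S1, S2], [(0, 1), (0, 0)])]
        )
        out = vm.impute_missing(t)
        assert out.missing_count() == 0
        assert all(not c.imputed for row in out.calls for c in row.values())

    def test_leaves_no_missing_and_preserves_mean_dp(self):
        rng = np.random.default_rng(7)
        sites = [Site("chr1", 100 * (i + 1), "A", "G", 0.2) for i in range(8)]
        patients = [f"P{j}" for j in range(5)]
        calls = []
        for _ in sites:
            row = {}
            for p in patients:
                if rng.random() < 0.3:
                    row[p] = SampleCall(None)
                else:
                    row[p] = SampleCall((0, 1), dp=int(rng.integers(10, 50)), pl=(40, 0, 40))
            calls.append(row)
        table = CallTable(sites=sites, patients=patients, calls=calls)
        called_dp = {
            p: [r[p].dp for r in table.calls if not r[p].is_missing] for p in patients
        }
        out = vm.impute_missing(table)
        assert out.missing_count() == 0
        for p in patients:
            imputed = [r[p].dp for r in out.calls if r[p].imputed]
            if imputed:
                assert all(d == round(float(np.mean(called_dp[p]))) for d in imputed)

    def test_zero_called_sites_names_patient(self):
        t = CallTable(
            sites=[Site("chr1", 100, "A", "G", 0.2)],
            patients=["P9"],
            calls=[{"P9": SampleCall(None)}],
        )
        with pytest.raises(vm.CannotImputeError, match="P9"):
            vm.impute_missing(t)


# ---------------------------------------------------------------------------
# to_patient_matrix / TSV round trip
# ---------------------------------------------------------------------------

def _full_table(n_patients=3, n_sites=2, seed=5):
    rng = np.random.default_rng(seed)
    sites = [Site("chr1", 100 * (i + 1), "A", "G", round(rng.uniform(0.1, 0.9), 3))
             for i in range(n_sites)]
    patients = [f"P{j}" for j in range(n_patients)]
    gts = [(0, 0), (0, 1), (1, 1)]
    calls = [
        {
            p: SampleCall(
                gts[rng.integers(3)], dp=int(rng.integers(10, 60)),
                pl=(0, 40, 80), imputed=bool(rng.random() < 0.3),
            )
            for p in patients
        }
        for _ in sites
    ]
    return CallTable(sites=sites, patients=patients, calls=calls)


class TestPatientMatrix:
    def test_single_patient_single_site_shape(self):
        t = _full_table(1, 1)
        m = vm.to_patient_matrix(t)
        assert m.data.shape == (1, 4)

    def test_four_columns_per_variant(self):
        m = vm.to_patient_matrix(_full_table(3, 5))
        assert m.data.shape == (3, 20)
        for key in m.site_keys:
            assert {f"{key}:{f}" for f in vm.FEATURE_FIELDS} <= set(m.data.columns)

    def test_gt_column_encodes_dosage(self):
        t = _full_table(3, 2)
        m = vm.to_patient_matrix(t)
        for i, site in enumerate(t.sites):
            for p in t.patients:
                assert m.dosage(p, site.key) == t.calls[i][p].dosage

    def test_transpose_is_involution(self):
        t = _full_table(3, 4)
        back = vm.from_patient_matrix(vm.to_patient_matrix(t))
        assert [s.key for s in back.sites] == [s.key for s in t.sites]
        for row_a, row_b in zip(t.calls, back.calls):
            for p in t.patients:
                assert row_a[p] == row_b[p]

    def test_refuses_missing_calls(self):
        with pytest.raises(ValueError, match="missing"):
            vm.to_patient_matrix(_table_with_missing())

    def test_tsv_round_trip_exact(self, tmp_path):
        m = vm.to_patient_matrix(_full_table(3, 4))
        path = tmp_path / "m.tsv"
        vm.write_tsv(m, path)
        back = vm.read_tsv(path)
        assert back.data.equals(m.data)
        assert back.imputed.astype(bool).equals(m.imputed.astype(bool))

    def test_empty_matrix_round_trip(self, tmp_path):
        import pandas as pd

        m = vm.PatientGenomicMatrix(
            data=pd.DataFrame(index=pd.Index([], name="patient")),
            imputed=pd.DataFrame(index=pd.Index([], name="patient")),
        )
        path = tmp_path / "empty.tsv"
        vm.write_tsv(m, path)
        assert path.read_text().splitlines()[0].startswith("patient")
        assert len(vm.read_tsv(path).data) == 0

    def test_column_mismatch_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("patient\tchr1:100:A>G:GT\timputed_sites\nP1\t0/1\n")
        with pytest.raises(vm.MatrixFormatError):
            vm.read_tsv(path)
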