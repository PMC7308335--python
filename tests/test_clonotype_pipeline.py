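import numpy as np
import pandas as pd
import pytest

from repscan import clonotype_pipeline as cp
from repscan import synthetic_data as sd
from repscan.io_core import (
    GermlineSegment,
    Read,
    RunConfig,
    read_fastq_pairs,
    registry_by_kind,
    revcomp,
)


def mkread(seq, qual=30):
    quals = (qual,) * len(seq) if isinstance(qual, int) else tuple(qual)
    return Read("r", seq, quals)


class TestJoin:
    def test_identical_full_length_mates(self):
        s = "ACGTACGTACGTACGTACGT"
        assert cp.join_read_pair(mkread(s), mkread(revcomp(s))) == s

    def test_partial_overlap_concatenation(self, rng):
        amp = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        r1 = mkread(amp[:25])
        r2 = mkread(revcomp(amp[17:]))  # 8-nt overlap with r1
        joined = cp.join_read_pair(r1, r2, min_overlap=8)
        assert joined == amp
        assert len(joined) == 25 + 23 - 8

    def test_higher_quality_base_wins(self):
        s1 = "ACGTACGTACGT"
        s2 = list(s1)
        s2[5] = "A" if s1[5] != "A" else "C"
        s2 = "".join(s2)
        r1 = mkread(s1, 10)
        r2 = mkread(revcomp(s2), 40)
        joined = cp.join_read_pair(r1, r2, min_overlap=10)
        assert joined[5] == s2[5]
        # tie goes to R1
        joined = cp.join_read_pair(mkread(s1, 30), mkread(revcomp(s2), 30),
                                   min_overlap=10)
        assert joined[5] == s1[5]

    def test_rejection_is_a_value(self):
        r1 = mkread("AAAAAAAAAAAA")
        r2 = mkread("AAAAAAAAAAAA")  # revcomp -> TTTT...: no valid overlap
        assert cp.join_read_pair(r1, r2, min_overlap=10, max_mismatch_frac=0.1) is None


class TestAssign:
    def test_error_free_read_recovers_truth(self, registry):
        params = sd.RepertoireSimParams(n_clonotypes=30, seed=21, error_rate=0.0)
        truth = sd.simulate_repertoire(params, registry)
        by = registry_by_kind(list(registry))
        for _, row in truth.head(10).iterrows():
            amp = sd.amplicon_sequence(row, by)
            got = cp.assign_v_j(amp, registry)
            assert got is not None
            v_name, j_name, v_anchor, j_anchor = got
            assert (v_name, j_name) == (row["v_name"], row["j_name"])
            assert amp[v_anchor : j_anchor + 3] == row["cdr3_nt"]

    def test_random_bases_rejected(self, registry, rng):
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        assert cp.assign_v_j(junk, registry) is None

    def test_tie_broken_lexicographically(self):
        shared = "CAATGCAGGTCTGCTCGGATTCAATGT" + "TGTGCCAGCAGT"
        va = GermlineSegment("TRBV8", "V", shared, anchor_offset=27)
        vb = GermlineSegment("TRBV9", "V", shared, anchor_offset=27)
        j = GermlineSegment("TRBJ9", "J",
                            "ACTACTTAAGAC" "TTCGGTGGAACCACTGAG", anchor_offset=12)
        read = shared + "ACGGA" + j.sequence
        got = cp.assign_v_j(read, [va, vb, j])
        assert got is not None and got[0] == "TRBV8"


class TestClusterMergeCutoff:
    def test_cluster_counts(self):
        assigned = pd.DataFrame([
            dict(v_name="V1", j_name="J1", cdr3_nt="AAA"),
            dict(v_name="V1", j_name="J1", cdr3_nt="AAA"),
            dict(v_name="V1", j_name="J1", cdr3_nt="AAC"),
        ])
        table = cp.cluster_clonotypes(assigned)
        assert sorted(table["read_count"]) == [1, 2]
        assert table["frequency"].sum() == pytest.approx(1.0)

    def test_cluster_empty(self):
        assert len(cp.cluster_clonotypes(pd.DataFrame())) == 0

    @staticmethod
    def _table(counts):
        rows = [dict(v_name="V1", j_name="J1", cdr3_nt=c, read_count=n)
                for c, n in counts.items()]
        df = pd.DataFrame(rows)
        df["frequency"] = df["read_count"] / df["read_count"].sum()
        return df

    def test_25_fold_neighbor_merges(self):
        table = self._table({"TGTGCCAAA": 10_000, "TGTGCCAAC": 400})
        merged = cp.merge_neighbor_clonotypes(table, 20.0)
        assert len(merged) == 1
        assert merged["read_count"].iloc[0] == 10_400

    def test_16_fold_neighbor_does_not_merge(self):
        table = self._table({"TGTGCCAAA": 10_000, "TGTGCCAAC": 600})
        merged = cp.merge_neighbor_clonotypes(table, 20.0)
        assert len(merged) == 2

    def test_no_neighbors_unchanged(self):
        table = self._table({"TGTGCCAAA": 100, "TTTTTTTTT": 90})
        merged = cp.merge_neighbor_clonotypes(table, 20.0)
        assert sorted(merged["read_count"]) == [90, 100]

    def test_merge_conserves_total_reads(self, rng):
        cdr3s = ["".join("ACGT"[i] for i in rng.integers(0, 4, 9)) for _ in range(40)]
        # add deliberate 1-bp neighbours
        cdr3s += [c[:-1] + ("A" if c[-1] != "A" else "C") for c in cdr3s[:10]]
        counts = {c: int(rng.integers(1, 5000)) for c in set(cdr3s)}
        table = self._table(counts)
        merged = cp.merge_neighbor_clonotypes(table, 20.0)
        assert merged["read_count"].sum() == table["read_count"].sum()
        assert merged["frequency"].sum() == pytest.approx(1.0)

    def test_cutoff_removes_strictly_below(self):
        df = pd.DataFrame(dict(v_name=["V"] * 3, j_name=["J"] * 3,
                               cdr3_nt=["A", "B", "C"],
                               read_count=[999_981, 9, 10]))
        df["frequency"] = df["read_count"] / 1_000_000
        kept = cp.apply_frequency_cutoff(df, 1e-5)
        assert set(kept["cdr3_nt"]) == {"A", "C"}  # 10 reads = exactly 0.001%
        # no renormalization
        assert kept["frequency"].tolist() == [999_981 / 1e6, 10 / 1e6]

    def test_cutoff_zero_keeps_everything(self):
        df = self._table({"AAA": 1, "CCC": 1})
        assert len(cp.apply_frequency_cutoff(df, 0.0)) == 2


class TestDecompose:
    def test_worked_example(self, worked_example_segments):
        v, d1, d2, j = worked_example_segments
        cdr3 = "TGTGCCAGCA" + "AC" + "GACAGGGG" + "T" + "CACCGGGCAGCTCTTC"
        arch = cp.decompose_architecture(cdr3, v, j, [d1, d2], min_d_match=5)
        assert arch.v_trunc == 2
        assert arch.d_name == "TRBD1"
        # "GACAGGGG" sits at offset 2 of GGGACAGGGGGC, leaving 2 nt each side
        assert (arch.d5_trunc, arch.d3_trunc) == (2, 2)
        assert (arch.n1_seq, arch.n2_seq) == ("AC", "T")
        assert arch.j_trunc == 2
        assert arch.cdr3_len == 37
        assert arch.functional is False  # 37 % 3 != 0

    def test_worked_example_in_frame(self, worked_example_segments):
        v, d1, d2, j = worked_example_segments
        cdr3 = "TGTGCCAGCA" + "C" + "GACAGGGG" + "T" + "CACCGGGCAGCTCTTC"
        arch = cp.decompose_architecture(cdr3, v, j, [d1, d2], min_d_match=5)
        assert arch.cdr3_len == 36
        assert arch.functional is True

    def test_short_d_match_reported_as_n1(self, worked_example_segments):
        v, d1, d2, j = worked_example_segments
        junction = "ACGGTCA"  # best D match in either D is < 5 nt
        cdr3 = "TGTGCCAGCAGT" + junction + "AACACCGGGCAGCTCTTC"
        arch = cp.decompose_architecture(cdr3, v, j, [d1, d2], min_d_match=5)
        assert arch.d_name == ""
        assert arch.n1_seq == junction
        assert arch.n2_seq == ""

    def test_reconstruction_identity(self, registry, by_kind):
        truth = sd.simulate_repertoire(
            sd.RepertoireSimParams(n_clonotypes=150, seed=31), registry)
        segmap = {s.name: s for s in registry}
        for _, row in truth.iterrows():
            v, j = segmap[row["v_name"]], segmap[row["j_name"]]
            arch = cp.decompose_architecture(row["cdr3_nt"], v, j, by_kind["D"])
            vpart = v.sequence[v.anchor_offset : len(v.sequence) - arch.v_trunc]
            jpart = j.sequence[arch.j_trunc : j.anchor_offset + 3]
            if arch.d_name:
                d = segmap[arch.d_name].sequence
                kept = d[arch.d5_trunc : len(d) - arch.d3_trunc]
                assert len(kept) >= 5
                rebuilt = vpart + arch.n1_seq + kept + arch.n2_seq + jpart
            else:
                rebuilt = vpart + arch.n1_seq + jpart
            assert rebuilt == row["cdr3_nt"]


class TestClosedLoop:
    def test_error_free_pipeline_recovers_truth_set(self, registry, tmp_path):
        params = sd.RepertoireSimParams(n_clonotypes=120, read_depth=3000,
                                        error_rate=0.0, seed=42)
        truth = sd.simulate_repertoire(params, registry)
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        sd.reads_from_repertoire(truth, params, registry, r1, r2)
        cfg = RunConfig(clonotype_frequency_cutoff=1e-9)
        table = cp.profile_reads(read_fastq_pairs(r1, r2), registry, cfg)
        counts = np.random.default_rng(params.seed + 1).multinomial(
            params.read_depth, truth["frequency"].to_numpy())
        covered = {k for k, c in zip(
            zip(truth["v_name"], truth["j_name"], truth["cdr3_nt"]), counts) if c > 0}
        got = set(zip(table["v_name"], table["j_name"], table["cdr3_nt"]))
        assert got == covered
        # architecture agreement except for coincidental germline extension
        tmap = {(r.v_name, r.j_name, r.cdr3_nt): r for r in truth.itertuples()}
        exact = sum(
            1 for r in table.itertuples()
            if (t := tmap[(r.v_name, r.j_name, r.cdr3_nt)]) is not None
            and r.d_name == t.d_name and r.n1_seq == t.n1_seq and r.n2_seq == t.n2_seq
        )
        assert exact >= 0.5 * len(table)

    def test_pipeline_deterministic(self, registry, tmp_path):
        params = sd.RepertoireSimParams(n_clonotypes=40, read_depth=600,
                                        error_rate=0.005, seed=43)
        truth = sd.simulate_repertoire(params, registry)
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        sd.reads_from_repertoire(truth, params, registry, r1, r2)
        t1 = cp.profile_reads(read_fastq_pairs(r1, r2), registry)
        t2 = cp.profile_reads(read_fastq_pairs(r1, r2), registry)
        pd.testing.assert_frame_equal(t1, t2)
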