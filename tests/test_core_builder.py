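import math

import pytest

from repcore import (
    AlleleDatabase,
    AlleleSequence,
    Segment,
    derive_d_cores,
    derive_d_lcs_cores,
    derive_j_cores,
    derive_v_cores,
)
from repcore.core_builder import (
    CoreBuildError,
    read_cores_fasta,
    write_cores_fasta,
)
from repcore.simulator import synthetic_reference


def vdb(*pairs):
    return AlleleDatabase(
        Segment.V, [AlleleSequence(n, s, Segment.V) for n, s in pairs]
    )


def jdb(*pairs):
    return AlleleDatabase(
        Segment.J, [AlleleSequence(n, s, Segment.J) for n, s in pairs]
    )


def ddb(*pairs):
    return AlleleDatabase(
        Segment.D, [AlleleSequence(n, s, Segment.D) for n, s in pairs]
    )


class TestVCores:
    def test_single_allele_default_trim(self):
        cores = derive_v_cores(vdb(("GA*01", "AAACCCGGGTTT")), 4, 6)
        assert cores.cores["GA*01"] == "AAACCCGG"
        assert cores.gene_trim["GA"] == (0, 4)

    def test_final_nucleotide_variant_keeps_full_length(self):
        db = vdb(("GA*01", "AAACCCGGACGTA"), ("GA*02", "AAACCCGGACGTC"))
        cores = derive_v_cores(db, 4, 6)
        assert cores.gene_trim["GA"] == (0, 0)
        assert cores.cores["GA*01"] == "AAACCCGGACGTA"
        assert cores.cores["GA*02"] == "AAACCCGGACGTC"

    def test_variant_at_offset_four_retained_by_default_trim(self):
        # alleles differ at 0-based offset 4 from the 3' end (the fifth-from-
        # last base): a 4 nt trim keeps it as the final core base
        a = "AAACCCGGGTTTAGCAT"
        b = a[:-5] + "C" + a[-4:]
        cores = derive_v_cores(vdb(("GA*01", a), ("GA*02", b)), 4, 6)
        assert cores.gene_trim["GA"] == (0, 4)
        assert cores.cores["GA*01"][-1] != cores.cores["GA*02"][-1]

    def test_trim_exceeding_length_is_error(self):
        with pytest.raises(CoreBuildError):
            derive_v_cores(vdb(("GA*01", "ACGT")), 4, 6)

    def test_length_only_difference_is_error(self):
        db = vdb(("GA*01", "AAACCCGGGTTTAA"), ("GA*02", "AAACCCGGGTTT"))
        with pytest.raises(CoreBuildError, match="GA"):
            derive_v_cores(db, 4, 6)

    def test_identical_cross_gene_cores_merged(self):
        shared = "AAACCCGGGTTTACGTACGT"
        db = vdb(("GA*01", shared + "AAAA"), ("GB*01", shared + "CCCC"))
        cores = derive_v_cores(db, 4, 6)
        assert list(cores.cores) == ["GA*01/GB*01"]
        assert cores.merged_groups == [["GA*01", "GB*01"]]

    def test_prefix_property(self):
        db = synthetic_reference("V", 10, [1, 2], (60, 70), seed=9)
        cores = derive_v_cores(db)
        for name, core in cores.cores.items():
            for part in name.split("/"):
                assert db[part].seq.startswith(core)

    def test_equal_trim_within_gene(self):
        db = synthetic_reference("V", 10, [2, 3], (60, 70), seed=10)
        cores = derive_v_cores(db)
        for gene, alleles in db.genes.items():
            trims = {
                len(a.seq) - len(cores.cores[n])
                for n, c in cores.cores.items()
                for part in n.split("/")
                if (a := db[part]).gene == gene
            }
            assert len(trims) == 1

    def test_determinism(self):
        db = synthetic_reference("V", 10, [1, 2], (60, 70), seed=9)
        assert derive_v_cores(db).cores == derive_v_cores(db).cores


class TestJCores:
    def test_five_prime_trim(self):
        cores = derive_j_cores(jdb(("JA*01", "ATTACTACTTTGACTACTGG")), 6)
        assert cores.cores["JA*01"] == "ACTTTGACTACTGG"
        assert cores.gene_trim["JA"] == (6, 0)

    def test_five_prime_variant_reduces_trim(self):
        a = "ATTACTACTTTGACTACTGG"
        b = a[:2] + "G" + a[3:]  # variant at 5' offset 2
        cores = derive_j_cores(jdb(("JA*01", a), ("JA*02", b)), 6)
        assert cores.gene_trim["JA"] == (2, 0)
        assert cores.cores["JA*01"][0] != cores.cores["JA*02"][0]

    def test_trim_at_least_length_is_error(self):
        with pytest.raises(CoreBuildError):
            derive_j_cores(jdb(("JA*01", "ACGTAC")), 6)


class TestDCores:
    def test_dual_end_trim(self):
        cores = derive_d_cores(ddb(("DA*01", "GTGGATATAGTGGCTACGATTAC")), 4, 4)
        assert cores.cores["DA*01"] == "ATATAGTGGCTACGA"

    def test_core_below_minimum_length_is_error(self):
        with pytest.raises(CoreBuildError, match="minimum"):
            derive_d_cores(ddb(("DA*01", "GTGGATATAGTGG")), 4, 4, min_core_len=8)

    def test_per_allele_trim_table_overrides_globals(self):
        db = ddb(
            ("DA*01", "GTGGATATAGTGGCTACGATTAC"),
            ("DB*01", "ACCTTGCAGTAGTACCAGCTGCT"),
        )
        cores = derive_d_cores(db, 4, 4, trim_table={"DA*01": (2, 2)})
        assert cores.cores["DA*01"] == "GGATATAGTGGCTACGATT"
        assert cores.cores["DB*01"] == "TGCAGTAGTACCAGC"
        assert cores.allele_trim == {"DA*01": (2, 2), "DB*01": (4, 4)}

    def test_non_gene_specific_core_is_error(self):
        inner = "ATATAGTGGCTACGA"
        db = ddb(
            ("DA*01", "GTGG" + inner + "TTAC"),
            ("DB*01", "CC" + inner + "GGAGAG"),  # contains DA's core
        )
        with pytest.raises(CoreBuildError, match="gene specific"):
            derive_d_cores(db, 4, 4)


class TestDLcsCores:
    def test_substring_enumeration_count(self):
        # single allele of length 10 at min_fraction 0.5: substring lengths
        # 5..10 give 6+5+4+3+2+1 = 21 retained substrings
        db = ddb(("DA*01", "GTGGATATAC"))
        dcores = derive_d_lcs_cores(db, 0.5)
        assert len(dcores.substrings["DA*01"]) == 21
        assert dcores.min_len["DA*01"] == 5

    def test_shared_substring_excluded_from_both(self):
        shared = "ATCGTAG"
        db = ddb(("DA*01", "GG" + shared + "CCAAT"), ("DB*01", "TT" + shared + "GACCA"))
        dcores = derive_d_lcs_cores(db, 0.5)
        assert shared not in dcores.substrings["DA*01"]
        assert shared not in dcores.substrings["DB*01"]

    def test_min_fraction_one_keeps_only_full_sequence(self):
        db = ddb(("DA*01", "GTGGATATAC"), ("DB*01", "CCATTGTAGC"))
        dcores = derive_d_lcs_cores(db, 1.0)
        assert dcores.substrings["DA*01"] == {"GTGGATATAC"}
        assert dcores.substrings["DB*01"] == {"CCATTGTAGC"}

    def test_duplicate_alleles_excluded_with_warning(self):
        db = ddb(("DA*01", "GTGGATATAC"), ("DB*01", "GTGGATATAC"))
        with pytest.warns(UserWarning, match="no allele-specific substring"):
            dcores = derive_d_lcs_cores(db, 1.0)
        assert dcores.substrings["DA*01"] == set()
        assert sorted(dcores.excluded) == ["DA*01", "DB*01"]

    def test_specificity_property_brute_force(self):
        db = synthetic_reference("D", 6, [1, 2], (14, 26), seed=17)
        dcores = derive_d_lcs_cores(db, 0.5)
        for a in db:
            m = math.ceil(0.5 * len(a.seq))
            for s in dcores.substrings[a.name]:
                assert len(s) >= m
                assert s in a.seq
                assert not any(s in b.seq for b in db if b.name != a.name)


def test_core_fasta_round_trip(tmp_path):
    db = synthetic_reference("V", 6, [1, 2], (50, 60), seed=4)
    cores = derive_v_cores(db)
    path = tmp_path / "cores.fasta"
    write_cores_fasta(cores, path)
    back = read_cores_fasta(path)
    assert back.cores == cores.cores
    assert back.segment == cores.segment
    assert back.gene_trim == cores.gene_trim
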