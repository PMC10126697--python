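import pytest

from repcore import (
    AlleleCount,
    FilterConfig,
    RearrangementRecord,
    batch_genotype,
    end_variant_test,
    filter_genotype,
    genotype_library,
    write_rearrangements,
)
from repcore.simulator import (
    SimConfig,
    full_heterozygous_genotype,
    simulate_library,
    synthetic_reference,
)


def make_count(name, raw, umi=None, n_cdr3=None, total=100_000, modal_share=0.2):
    """A diverse-CDR3 count: passes the clonal filters unless told otherwise."""
    umi = raw if umi is None else umi
    n_cdr3 = max(1, raw // 2) if n_cdr3 is None else n_cdr3
    modal = max(1, int(raw * modal_share))
    hist = {45: modal}
    rest = raw - modal
    length = 30
    while rest > 0:
        chunk = min(max(1, modal // 2), rest)
        hist[length] = chunk
        rest -= chunk
        length += 3
    return AlleleCount(
        allele=name,
        raw_count=raw,
        umi_count=umi,
        cdr3_len_hist=hist,
        unique_cdr3=n_cdr3,
        total_rows=total,
    )


def in_set(table):
    return set(table[table.in_genotype].allele)


class TestFilterGenotype:
    def test_allelic_ratio(self):
        counts = {
            "G*01": make_count("G*01", 1000),
            "G*02": make_count("G*02", 150),
            "G*03": make_count("G*03", 5),
        }
        table = filter_genotype(counts, FilterConfig(count_basis="raw"))
        assert in_set(table) == {"G*01", "G*02"}
        ratios = dict(zip(table.allele, table.allelic_ratio))
        assert ratios["G*02"] == pytest.approx(0.15)
        assert ratios["G*03"] == pytest.approx(0.005)

    def test_expected_frequency_rescue(self):
        # ratio 0.06 < 0.1 but library frequency clears the table minimum
        counts = {
            "G*01": make_count("G*01", 1000, total=200_000),
            "G*02": make_count("G*02", 60, total=200_000),  # freq 3e-4
        }
        config = FilterConfig(
            count_basis="raw", expected_freq_table={"G*02": 1e-4}
        )
        table = filter_genotype(counts, config).set_index("allele")
        assert bool(table.loc["G*02", "rescued"])
        assert bool(table.loc["G*02", "in_genotype"])

    def test_expected_frequency_excludes_below_minimum(self):
        counts = {
            "G*01": make_count("G*01", 1000, total=1_000_000),
            "H*01": make_count("H*01", 40, total=1_000_000),  # freq 4e-5
        }
        config = FilterConfig(
            count_basis="raw", expected_freq_table={"H*01": 1e-4}
        )
        table = filter_genotype(counts, config).set_index("allele")
        assert not bool(table.loc["H*01", "in_genotype"])

    def test_clonal_expansion_removed(self):
        # 40 matches, all one CDR3 sequence of one length
        clone = AlleleCount(
            allele="G*02",
            raw_count=40,
            umi_count=40,
            cdr3_len_hist={45: 40},
            unique_cdr3=1,
            total_rows=100_000,
        )
        counts = {"G*01": make_count("G*01", 100), "G*02": clone}
        table = filter_genotype(counts, FilterConfig(count_basis="raw"))
        row = table.set_index("allele").loc["G*02"]
        assert not row.pass_cdr3_len and not row.pass_cdr3_div
        assert in_set(table) == {"G*01"}

    def test_rescue_never_overrides_clonal_filters(self):
        clone = AlleleCount(
            allele="G*02",
            raw_count=40,
            umi_count=40,
            cdr3_len_hist={45: 40},
            unique_cdr3=1,
            total_rows=100_000,
        )
        counts = {"G*01": make_count("G*01", 10_000), "G*02": clone}
        config = FilterConfig(
            count_basis="raw", expected_freq_table={"G*02": 1e-5}
        )
        table = filter_genotype(counts, config)
        assert "G*02" not in in_set(table)

    def test_min_count(self):
        counts = {"G*01": make_count("G*01", 9)}
        assert in_set(filter_genotype(counts, FilterConfig(count_basis="raw"))) == set()

    def test_umi_basis_selected_automatically(self):
        counts = {"G*01": make_count("G*01", 50, umi=8)}
        assert in_set(filter_genotype(counts, FilterConfig())) == set()
        assert in_set(filter_genotype(counts, FilterConfig(count_basis="raw"))) == {
            "G*01"
        }

    def test_empty_counts_empty_table(self):
        assert filter_genotype({}, FilterConfig()).empty

    def test_top_allele_has_ratio_one(self):
        counts = {
            "G*01": make_count("G*01", 700),
            "G*02": make_count("G*02", 400),
            "H*01": make_count("H*01", 30),
        }
        table = filter_genotype(counts, FilterConfig(count_basis="raw"))
        top = table.groupby("gene")["allelic_ratio"].max()
        assert (top == 1.0).all()

    @pytest.mark.parametrize(
        "stricter",
        [
            {"allelic_ratio": 0.3},
            {"min_count": 200},
            {"lenmaxfreq": 0.15},
            {"min_unique_cdr3_frac": 0.6},
        ],
    )
    def test_filter_monotonicity(self, stricter):
        counts = {
            "G*01": make_count("G*01", 1000),
            "G*02": make_count("G*02", 150, n_cdr3=60),
            "H*01": make_count("H*01", 90),
        }
        base = in_set(filter_genotype(counts, FilterConfig(count_basis="raw")))
        tightened = in_set(
            filter_genotype(counts, FilterConfig(count_basis="raw", **stricter))
        )
        assert tightened <= base

    def test_unknown_table_allele_warns(self):
        counts = {"G*01": make_count("G*01", 100)}
        config = FilterConfig(count_basis="raw", expected_freq_table={"Z*01": 1e-3})
        with pytest.warns(UserWarning, match="unknown"):
            filter_genotype(counts, config)


@pytest.fixture(scope="module")
def small_dbs():
    return {
        "V": synthetic_reference("V", 6, [1, 2], (120, 130), seed=31),
        "D": synthetic_reference("D", 4, [1], (18, 24), seed=32),
        "J": synthetic_reference("J", 3, [1], (48, 52), seed=33),
    }


@pytest.fixture(scope="module")
def small_library(small_dbs):
    genotype = full_heterozygous_genotype(small_dbs)
    config = SimConfig(
        seed=41,
        n_reads=4000,
        usage_orders={"V": 0.5, "D": 0.5, "J": 0.5},
        per_base_error=0.0,
    )
    records, truth = simulate_library(genotype, small_dbs, config)
    return records, truth


class TestGenotypeLibrary:
    def test_recovers_simulated_genotype(self, small_dbs, small_library):
        records, truth = small_library
        table = genotype_library(records, small_dbs["V"])
        assert in_set(table) == truth.allele_names("V")

    def test_empty_library_all_out(self, small_dbs):
        table = genotype_library([], small_dbs["V"])
        assert not table.in_genotype.any()
        assert (table.raw_count == 0).all()

    def test_every_core_reported_once(self, small_dbs, small_library):
        records, _ = small_library
        table = genotype_library(records, small_dbs["V"])
        assert table.allele.is_unique
        assert len(table) == len(small_dbs["V"])  # no cross-gene merges here


class TestBatchGenotype:
    def test_columns_match_single_library_runs(self, small_dbs, small_library, tmp_path):
        records, _ = small_library
        paths = []
        for i, seed in enumerate((1, 2)):
            config = SimConfig(
                seed=seed,
                n_reads=2000,
                usage_orders={"V": 0.5, "D": 0.5, "J": 0.5},
                per_base_error=0.0,
            )
            recs, _ = simulate_library(
                full_heterozygous_genotype(small_dbs), small_dbs, config
            )
            p = tmp_path / f"lib{i}.tsv"
            write_rearrangements(recs, p)
            paths.append(p)
        result = batch_genotype(paths, small_dbs["V"])
        assert not result.failures
        for label, table in result.tables.items():
            column = result.matrix[label]
            expected = table.set_index("allele")["in_genotype"]
            assert column.reindex(expected.index).equals(expected)

    def test_identical_library_identical_columns(self, small_dbs, small_library, tmp_path):
        records, _ = small_library
        p = tmp_path / "lib.tsv"
        write_rearrangements(records, p)
        result = batch_genotype([p, p], small_dbs["V"], labels=["a", "b"])
        assert result.matrix["a"].equals(result.matrix["b"])

    def test_failing_library_isolated(self, small_dbs, small_library, tmp_path):
        records, _ = small_library
        good = tmp_path / "good.tsv"
        write_rearrangements(records, good)
        bad = tmp_path / "bad.tsv"
        bad.write_text("wrong_column\nACGT\n")
        result = batch_genotype([good, bad], small_dbs["V"], labels=["good", "bad"])
        assert "bad" in result.failures
        assert list(result.tables) == ["good"]
        assert list(result.matrix.columns) == ["good"]


class TestEndVariantTest:
    def test_modified_reads_yield_variant_allele(self, small_dbs, small_library):
        records, truth = small_library
        target = small_dbs["V"]["SIMV2*01"]
        new_base = "G" if target.seq[-1] != "G" else "C"
        table = end_variant_test(records, target, 1, new_base, small_dbs["V"])
        present = in_set(table)
        assert f"SIMV2*01_{new_base}" in present
        assert "SIMV2*01" not in present
        # the heterozygous partner allele is unaffected
        assert "SIMV2*02" in present

    def test_same_base_rejected(self, small_dbs, small_library):
        records, _ = small_library
        target = small_dbs["V"]["SIMV2*01"]
        with pytest.raises(ValueError, match="equals the original"):
            end_variant_test(records, target, 1, target.seq[-1], small_dbs["V"])

    def test_absent_target_is_error(self, small_dbs):
        target = small_dbs["V"]["SIMV2*01"]
        new_base = "G" if target.seq[-1] != "G" else "C"
        records = [RearrangementRecord(row_id=0, sequence="ACGT" * 50)]
        with pytest.raises(ValueError, match="no full-length occurrences"):
            end_variant_test(records, target, 1, new_base, small_dbs["V"])
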