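"""Round-trip and schema behaviour of the tabular readers/writers."""

import numpy as np
import pandas as pd
import pytest

from mistloo.cohort_io import (
    TableDialect,
    load_study,
    read_gene_results,
    read_phenotype_table,
    read_variant_table,
    write_gene_results,
    write_variant_table,
)
from mistloo.types import ConsistencyError, SchemaError, VariantRecord


def _toy_table(tmp_path, rows, samples=("a", "b", "c", "d")):
    cols = ["chrom", "pos", "ref", "alt", "gene", "vclass", "cadd"]
    cols += [f"gt_{s}" for s in samples]
    df = pd.DataFrame(rows, columns=cols)
    path = tmp_path / "variants.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


ROWS = [
    ["1", 100, "A", "C", "G1", "missense", 10.0, 0, 1, 0, 0],
    ["1", 200, "G", "T", "G1", "nonsense", 30.0, 0, 0, 1, 0],
    ["1", 150, "C", "G", "G1", "splicing", 20.0, 1, 0, 0, 0],
    ["1", 300, "T", "A", "G1", "missense", 5.0, 0, 0, 0, 2],
    ["2", 50, "A", "G", "G2", "frameshift", 35.0, 0, 1, 0, 0],
    ["2", 90, "C", "T", "G2", "missense", 8.0, 0, 0, 0, 1],
]


def test_variant_table_groups_genes_and_sorts(tmp_path):
    """Two genes with 4 and 2 variants; unsorted input comes out ordered."""
    path = _toy_table(tmp_path, ROWS)
    samples, regions = read_variant_table(path)
    assert samples == ["a", "b", "c", "d"]
    assert [r.gene for r in regions] == ["G1", "G2"]
    assert [r.n_variants for r in regions] == [4, 2]
    g1 = regions[0]
    assert [v.pos for v in g1.variants] == [100, 150, 200, 300]
    # genotype columns follow the sort: the pos-150 variant is carried by 'a'
    assert g1.G[0, 1] == 1.0


def test_duplicate_variant_row_kept_once(tmp_path, caplog):
    rows = ROWS + [ROWS[0]]
    path = _toy_table(tmp_path, rows)
    with caplog.at_level("WARNING"):
        _, regions = read_variant_table(path)
    assert regions[0].n_variants == 4
    assert any("duplicated" in r.message for r in caplog.records)


def test_round_trip_preserves_order_and_missing(tmp_path):
    path = _toy_table(tmp_path, ROWS)
    samples, regions = read_variant_table(path)
    regions[0].G[2, 0] = np.nan  # plant a missing call
    out = tmp_path / "rt.tsv"
    write_variant_table(samples, regions, out)
    samples2, regions2 = read_variant_table(out)
    assert samples2 == samples
    for r1, r2 in zip(regions, regions2):
        assert [v.key for v in r1.variants] == [v.key for v in r2.variants]
        np.testing.assert_array_equal(r1.G, r2.G)
    assert np.isnan(regions2[0].G[2, 0])


def test_permuted_input_rows_give_identical_regions(tmp_path):
    p1 = _toy_table(tmp_path, ROWS)
    rng = np.random.default_rng(3)
    shuffled = [ROWS[i] for i in rng.permutation(len(ROWS))]
    p2 = tmp_path / "shuffled.tsv"
    pd.DataFrame(shuffled, columns=pd.read_csv(p1, sep="\t").columns).to_csv(
        p2, sep="\t", index=False
    )
    _, ra = read_variant_table(p1)
    _, rb = read_variant_table(p2)
    for x, y in zip(ra, rb):
        assert [v.key for v in x.variants] == [v.key for v in y.variants]
        np.testing.assert_array_equal(x.G, y.G)


def test_missing_required_column_names_it(tmp_path):
    df = pd.DataFrame({"chrom": ["1"], "pos": [1], "ref": ["A"],
                       "alt": ["C"], "gene": ["G"], "gt_a": [0]})
    path = tmp_path / "bad.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(SchemaError, match="vclass"):
        read_variant_table(path)


@pytest.mark.parametrize(
    "statuses,expected_sum",
    [(["case"] * 3 + ["control"] * 5, 3), (["control"] * 4, 0)],
)
def test_phenotype_table_encoding(tmp_path, statuses, expected_sum):
    df = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(len(statuses))],
         "status": statuses}
    )
    path = tmp_path / "ph.tsv"
    df.to_csv(path, sep="\t", index=False)
    cohort = read_phenotype_table(path)
    assert cohort.y.sum() == expected_sum
    assert cohort.X.shape == (len(statuses), 1)


def test_phenotype_covariate_column(tmp_path):
    df = pd.DataFrame(
        {"sample_id": ["s0", "s1", "s2"], "status": ["case", "control", "1"],
         "age": [60, 55, 70]}
    )
    path = tmp_path / "ph.tsv"
    df.to_csv(path, sep="\t", index=False)
    cohort = read_phenotype_table(path)
    assert cohort.X.shape == (3, 2)
    np.testing.assert_array_equal(cohort.X[:, 1], [60, 55, 70])


def test_phenotype_errors(tmp_path):
    path = tmp_path / "ph.tsv"
    pd.DataFrame({"sample_id": ["a", "a"], "status": ["case", "control"]}
                 ).to_csv(path, sep="\t", index=False)
    with pytest.raises(ConsistencyError):
        read_phenotype_table(path)
    pd.DataFrame({"sample_id": ["a"], "status": ["maybe"]}).to_csv(
        path, sep="\t", index=False
    )
    with pytest.raises(SchemaError):
        read_phenotype_table(path)


def test_gene_results_sorted_and_round_trip(tmp_path):
    df = pd.DataFrame({"gene": ["A", "B", "C"], "p": [0.5, 0.01, 0.2],
                       "q": [0.6, 0.03, 0.3], "flags": ["", "", ""]})
    path = tmp_path / "res.tsv"
    write_gene_results(df, path)
    back = read_gene_results(path)
    assert back["p"].tolist() == [0.01, 0.2, 0.5]
    # 12-significant-digit round trip
    df2 = pd.DataFrame({"gene": ["X"], "p": [0.123456789012345],
                        "q": [1e-17], "flags": [""]})
    write_gene_results(df2, path)
    back2 = read_gene_results(path)
    assert back2["p"][0] == pytest.approx(0.123456789012345, rel=1e-11)


def test_empty_results_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_gene_results(pd.DataFrame(columns=["gene", "p", "q"]), path)
    assert read_gene_results(path).empty


def test_load_study_aligns_samples(tmp_path):
    vpath = _toy_table(tmp_path, ROWS)
    # phenotype table in a different sample order
    pd.DataFrame(
        {"sample_id": ["d", "a", "b", "c"],
         "status": ["case", "control", "case", "control"]}
    ).to_csv(tmp_path / "ph.tsv", sep="\t", index=False)
    cohort, regions = load_study(vpath, tmp_path / "ph.tsv")
    assert cohort.sample_ids == ["a", "b", "c", "d"]
    np.testing.assert_array_equal(cohort.y, [0, 1, 0, 1])


def test_vcf_reader_matches_tsv(tmp_path):
    """Genotypes from a small VCF equal the TSV route; annotation joined."""
    cyvcf2 = pytest.importorskip("cyvcf2")  # noqa: F841
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=1>\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
        "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t0/0\n"
        "1\t200\t.\tG\tT,C\t.\tPASS\t.\tGT\t1/2\t./.\n"
    )
    ann = pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "pos": [100, 200, 200],
            "ref": ["A", "G", "G"],
            "alt": ["C", "T", "C"],
            "gene": ["G1", "G1", "G1"],
            "vclass": ["missense", "nonsense", "missense"],
            "cadd": [10.0, 25.0, 3.0],
        }
    )
    from mistloo.cohort_io import read_vcf

    samples, regions = read_vcf(vcf, ann)
    assert samples == ["a", "b"]
    region = regions[0]
    assert region.n_variants == 3  # multi-allelic decomposed
    G = region.G
    np.testing.assert_array_equal(G[:, 0], [1.0, 0.0])  # 0/1, 0/0
    np.testing.assert_array_equal(G[0, 1:], [1.0, 1.0])  # 1/2 per allele
    assert np.isnan(G[1, 1]) and np.isnan(G[1, 2])  # ./.


def test_variant_record_validation():
    with pytest.raises(ValueError):
        VariantRecord("1", 0, "A", "C", "G", "missense")
    with pytest.raises(ValueError):
        VariantRecord("1", 5, "A", "C", "G", "weird_class")
    with pytest.raises(ValueError):
        VariantRecord("1", 5, "A", "C", "G", "missense", cadd=-1.0)
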