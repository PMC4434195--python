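"""I/O, allele-frequency and cleaning-filter unit tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedstrat import genoio


def _matrix(dosage, ref="A", alt="C"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {"id": [f"v{j}" for j in range(m)], "chrom": "3",
         "pos": np.arange(1, m + 1) * 10, "ref": ref, "alt": alt}
    )
    samples = pd.DataFrame({"fid": "1", "iid": [f"i{i}" for i in range(n)]})
    return genoio.GenotypeMatrix(dosage, variants, samples)


class TestRoundTrips:
    def test_ped_map_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(5, 10)).astype(float)
        dosage[0, 0] = np.nan
        gm = _matrix(dosage)
        genoio.write_ped_map(gm, tmp_path / "toy")
        back, _ = genoio.read_ped_map(tmp_path / "toy")
        np.testing.assert_array_equal(back.dosage, gm.dosage)
        pd.testing.assert_frame_equal(back.variants, gm.variants)
        assert back.iids == gm.iids

    def test_four_column_map_infers_minor_allele(self, tmp_path):
        gm = _matrix([[0, 2], [1, 2], [0, 2], [0, 1]])
        genoio.write_ped_map(gm, tmp_path / "toy")
        # strip the extended allele columns
        lines = [" ".join(l.split()[:4]) for l in (tmp_path / "toy.map").read_text().splitlines()]
        (tmp_path / "toy.map").write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="minor allele"):
            back, _ = genoio.read_ped_map(tmp_path / "toy")
        # column 0: alt 'C' is minor -> orientation preserved by luck of counts
        np.testing.assert_array_equal(back.dosage[:, 0], gm.dosage[:, 0])

    def test_vcf_round_trip(self, tmp_path):
        dosage = np.array([[0, 1, 2], [2, np.nan, 0]])
        gm = _matrix(dosage)
        genoio.write_vcf(gm, tmp_path / "toy.vcf")
        back = genoio.read_vcf(tmp_path / "toy.vcf")
        np.testing.assert_array_equal(back.dosage, gm.dosage)
        assert back.variants["alt"].tolist() == gm.variants["alt"].tolist()
        assert back.iids == gm.iids

    def test_vcf_het_is_dosage_one(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "3\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\n"
        )
        gm = genoio.read_vcf(vcf)
        assert gm.dosage[0, 0] == 1.0

    def test_bad_allele_raises(self, tmp_path):
        gm = _matrix([[0, 1], [1, 2]])
        genoio.write_ped_map(gm, tmp_path / "toy")
        ped = (tmp_path / "toy.ped").read_text().replace("A C", "A T", 1)
        (tmp_path / "toy.ped").write_text(ped)
        with pytest.raises(genoio.DataError, match="declared pair"):
            genoio.read_ped_map(tmp_path / "toy")

    def test_malformed_line_reports_line_number(self, tmp_path):
        gm = _matrix([[0, 1], [1, 2]])
        genoio.write_ped_map(gm, tmp_path / "toy")
        with open(tmp_path / "toy.ped", "a") as fh:
            fh.write("1 extra 0 0 1 -9 A\n")
        with pytest.raises(genoio.ParseError, match=":3: expected"):
            genoio.read_ped_map(tmp_path / "toy")


class TestFrequencies:
    def test_single_group_arithmetic(self):
        gm = _matrix(np.array([[0], [1], [2], [2]]))
        f = genoio.compute_freq(gm)
        assert f.loc[0, "p_alt"] == pytest.approx(5 / 8)
        assert f.loc[0, "maf"] == pytest.approx(3 / 8)
        assert f.loc[0, "n_alleles"] == 8

    def test_all_reference(self):
        f = genoio.compute_freq(_matrix(np.zeros((4, 1))))
        assert f.loc[0, "p_alt"] == 0.0 and f.loc[0, "maf"] == 0.0

    def test_all_missing_is_undefined_not_zero(self):
        f = genoio.compute_freq(_matrix(np.full((3, 1), np.nan)))
        assert np.isnan(f.loc[0, "p_alt"])
        assert f.loc[0, "n_alleles"] == 0

    def test_matches_bruteforce_tally_with_missingness(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(20, 15)).astype(float)
        dosage[rng.random(dosage.shape) < 0.2] = np.nan
        gm = _matrix(dosage)
        groups = {f"i{i}": ("a" if i < 12 else "b") for i in range(20)}
        table = genoio.compute_freq(gm, groups)
        for j in range(15):
            for label, rows in (("a", range(12)), ("b", range(12, 20))):
                vals = [dosage[i, j] for i in rows if not np.isnan(dosage[i, j])]
                row = table[(table["variant_id"] == f"v{j}") & (table["group"] == label)].iloc[0]
                if not vals:
                    assert np.isnan(row["p_alt"])
                else:
                    assert row["p_alt"] == pytest.approx(sum(vals) / (2 * len(vals)))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 1.0, 2.0, np.nan]), min_size=4, max_size=30),
           st.integers(min_value=1, max_value=29))
    def test_union_is_count_weighted_average_of_groups(self, values, split):
        split = min(split, len(values) - 1)
        dosage = np.asarray(values, dtype=float)[:, None]
        gm = _matrix(dosage)
        groups = {f"i{i}": ("a" if i < split else "b") for i in range(len(values))}
        t = genoio.compute_freq(gm, groups).set_index("group")
        whole = genoio.compute_freq(gm).iloc[0]
        na, nb = t.loc["a", "n_alleles"], t.loc["b", "n_alleles"]
        if na + nb == 0:
            assert np.isnan(whole["p_alt"])
        else:
            pa = 0.0 if na == 0 else t.loc["a", "p_alt"]
            pb = 0.0 if nb == 0 else t.loc["b", "p_alt"]
            assert whole["p_alt"] == pytest.approx((pa * na + pb * nb) / (na + nb))


class TestMafFilter:
    def test_strictly_greater_than_threshold(self):
        # 100 individuals -> 200 alleles; alt counts 10, 20, 22
        dosage = np.zeros((100, 3))
        dosage[:10, 0] = 1.0
        dosage[:20, 1] = 1.0
        dosage[:22, 2] = 1.0
        gm = _matrix(dosage)
        kept = genoio.filter_maf(gm, threshold=0.1)
        assert kept.variant_ids == ["v2"]  # 0.11 only; 0.10 excluded (strict)

    def test_zero_threshold_keeps_polymorphic(self):
        dosage = np.array([[0, 0, 1], [0, 1, 1]], dtype=float)
        kept = genoio.filter_maf(_matrix(dosage), threshold=0.0)
        assert kept.variant_ids == ["v1", "v2"]  # monomorphic v0 dropped

    def test_half_threshold_keeps_nothing(self):
        dosage = np.array([[0, 1], [1, 2]], dtype=float)
        kept = genoio.filter_maf(_matrix(dosage), threshold=0.5)
        assert kept.n_variants == 0

    def test_surviving_variants_satisfy_threshold(self, small_data):
        kept = genoio.filter_maf(small_data.genotypes, threshold=0.1)
        f = genoio.compute_freq(kept)
        assert (f["maf"] > 0.1).all()


def _family(dosages: dict) -> tuple[genoio.GenotypeMatrix, genoio.Pedigree]:
    ped = genoio.Pedigree(
        pd.DataFrame(
            {
                "fid": "1",
                "iid": ["f", "m", "c"],
                "father": ["0", "0", "f"],
                "mother": ["0", "0", "m"],
                "sex": [1, 2, 2],
                "founder": [True, True, False],
            }
        )
    )
    dosage = np.array([[dosages["f"]], [dosages["m"]], [dosages["c"]]], dtype=float)
    return _matrix_with_iids(dosage, ["f", "m", "c"]), ped


def _matrix_with_iids(dosage, iids):
    n, m = dosage.shape
    variants = pd.DataFrame(
        {"id": [f"v{j}" for j in range(m)], "chrom": "3",
         "pos": np.arange(1, m + 1), "ref": "A", "alt": "C"}
    )
    return genoio.GenotypeMatrix(dosage, variants, pd.DataFrame({"fid": "1", "iid": iids}))


class TestMendel:
    @pytest.mark.parametrize(
        "trio,expect",
        [
            ({"f": 0, "m": 0, "c": 1}, 1),
            ({"f": 2, "m": 2, "c": 1}, 1),
            ({"f": 0, "m": 2, "c": 0}, 1),  # must be het
            ({"f": 0, "m": 0, "c": 0}, 0),
            ({"f": 1, "m": 1, "c": 0}, 0),
            ({"f": 1, "m": 1, "c": 1}, 0),
            ({"f": 1, "m": 1, "c": 2}, 0),
            ({"f": 0, "m": np.nan, "c": 2}, 1),  # father can't transmit alt
        ],
    )
    def test_trio_rules(self, trio, expect):
        gm, ped = _family(trio)
        assert len(genoio.mendel_check(gm, ped)) == expect

    def test_gene_drop_output_is_clean(self, small_data):
        v = genoio.mendel_check(small_data.genotypes, small_data.pedigree)
        assert len(v) == 0

    def test_filter_removes_offending_variants(self):
        gm, ped = _family({"f": 0, "m": 0, "c": 2})
        v = genoio.mendel_check(gm, ped)
        assert genoio.filter_mendel(gm, v).n_variants == 0
        assert genoio.filter_mendel(gm, v, max_violations=1).n_variants == 1


class TestPedigreeValidation:
    def test_cycle_detected(self):
        bad = genoio.Pedigree(
            pd.DataFrame(
                {
                    "fid": "1", "iid": ["a", "b"],
                    "father": ["b", "a"], "mother": ["b", "a"],
                    "sex": [1, 1], "founder": [False, False],
                }
            )
        )
        with pytest.raises(genoio.DataError):
            bad.validate()

    def test_fam_round_trip(self, tmp_path, small_data):
        small_data.pedigree.write_fam(tmp_path / "x.fam")
        back = genoio.Pedigree.read_fam(tmp_path / "x.fam")
        pd.testing.assert_frame_equal(back.table, small_data.pedigree.table)
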