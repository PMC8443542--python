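"""Distances, outlier flagging, translation/AGCT screens, barcode gaps."""

import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barcodekit.align_trim import MSA
from barcodekit.cleaning import (
    GENETIC_CODES,
    BarcodeGapRow,
    CleanConfig,
    agct_check,
    barcode_gap_report,
    clean_dataset,
    clean_file,
    flag_distance_outliers,
    p_distance_matrix,
    translation_check,
)
from barcodekit.synthetic import FixtureSpec, generate_fixture


def msa_of(rows: dict) -> MSA:
    return MSA(ids=list(rows), rows=list(rows.values()))


# --- independent oracles -------------------------------------------------

def brute_p_distance(a: str, b: str):
    """Position-by-position pairwise-deletion oracle."""
    comp = mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            comp += 1
            if x != y:
                mism += 1
    return (mism / comp if comp else None), comp


def brute_gap_rows(ids, dmat, species):
    rows = {}
    for sp in sorted(set(species.values())):
        members = [i for i, sid in enumerate(ids) if species[sid] == sp]
        others = [i for i in range(len(ids)) if i not in members]
        intra = [
            dmat[i][j]
            for i in members for j in members
            if i < j and dmat[i][j] is not None
        ]
        inter = [
            dmat[i][j] for i in members for j in others
            if dmat[i][j] is not None
        ]
        mi = max(intra) if intra else None
        mn = min(inter) if inter else None
        rows[sp] = (len(members), mi, mn,
                    (mn > mi) if mi is not None and mn is not None else None)
    return rows


def tukey_outlier_oracle(means, multiplier=1.5):
    """Quartiles via the statistics module (inclusive = linear interp)."""
    q1, _, q3 = statistics.quantiles(means, n=4, method="inclusive")
    fence = q3 + multiplier * (q3 - q1)
    return {i for i, m in enumerate(means) if m > fence}


# --- p-distance ----------------------------------------------------------

class TestPDistance:
    @pytest.mark.parametrize(
        ("a", "b", "d", "sites"),
        [
            ("AAAA", "AAAA", 0.0, 4),
            ("AAAA", "AAAT", 0.25, 4),
            ("AA-A", "AATA", 0.0, 3),
            ("ANNA", "AATA", 0.0, 2),
            ("----", "AAAA", None, 0),
        ],
    )
    def test_pairwise_deletion_examples(self, a, b, d, sites):
        dm = p_distance_matrix(msa_of({"a": a, "b": b}))
        got = dm.d[0, 1]
        if d is None:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(d)
        assert dm.n_sites[0, 1] == sites

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            p_distance_matrix(msa_of({"a": "ACGT"}))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(10, 120))
        alphabet = list("ACGTN-")
        a = "".join(rng.choice(alphabet, size=length, p=[0.2] * 4 + [0.1, 0.1]))
        b = "".join(rng.choice(alphabet, size=length, p=[0.2] * 4 + [0.1, 0.1]))
        dm = p_distance_matrix(msa_of({"a": a, "b": b}))
        expect, sites = brute_p_distance(a, b)
        assert dm.n_sites[0, 1] == sites
        if expect is None:
            assert np.isnan(dm.d[0, 1])
        else:
            assert dm.d[0, 1] == pytest.approx(expect)

    def test_symmetry_and_zero_diagonal(self):
        fx = generate_fixture(FixtureSpec(seed=3, n_ambig=0, n_stop=0))
        dm = p_distance_matrix(
            msa_of({h: s for h, s in fx.records})
        )
        assert np.allclose(dm.d, dm.d.T, equal_nan=True)
        assert np.all(np.diag(dm.d) == 0)


# --- outlier flagging ----------------------------------------------------

class TestDistanceOutliers:
    def _dm(self, seqs):
        return p_distance_matrix(msa_of(seqs))

    def test_divergent_member_flagged(self):
        """Nine near-identical sequences and one at ~30% divergence: only
        the divergent member crosses 1.5x the group mean."""
        fx = generate_fixture(
            FixtureSpec(seed=5, n_clean=9, n_ambig=0, n_stop=0,
                        species_partition=(9,))
        )
        dm = self._dm({h: s for h, s in fx.records})
        groups = {h: "G" for h, _ in fx.records}
        got = flag_distance_outliers(dm, groups)
        assert got == {h for h, _ in fx.records if "SYNO" in h}

    def test_identical_sequences_no_outliers(self):
        dm = self._dm({f"s{i}": "ACGTACGT" for i in range(5)})
        assert flag_distance_outliers(dm, {f"s{i}": "G" for i in range(5)}) == set()

    def test_small_groups_are_skipped(self):
        dm = self._dm({"s0": "AAAAAAAA", "s1": "TTTTTTTT"})
        got = flag_distance_outliers(
            dm, {"s0": "G", "s1": "G"}, min_group_size=4
        )
        assert got == set()

    @given(st.integers(0, 2**31 - 1))
    def test_tukey_mode_matches_independent_quartiles(self, seed):
        """The tukey switch reproduces an independent quartile/fence
        implementation on random distance structures."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        pts = rng.random(n)  # 1-D "positions" -> distance |xi - xj|
        d = np.abs(pts[:, None] - pts[None, :])
        ids = [f"s{i}" for i in range(n)]
        dm = p_distance_matrix(msa_of({i: "ACGT" for i in ids}))
        dm.d = d
        dm.n_sites = np.full((n, n), 4)
        got = flag_distance_outliers(
            dm, {i: "G" for i in ids}, method="tukey", min_group_size=2
        )
        means = [np.delete(d[i], i).mean() for i in range(n)]
        expect = {ids[i] for i in tukey_outlier_oracle(means)}
        assert got == expect


# --- translation & AGCT screens ------------------------------------------

class TestGeneticCodes:
    def test_code_tables_have_64_codons(self):
        for code in GENETIC_CODES.values():
            assert len(code.table) == 64

    def test_stop_codon_sets(self):
        assert GENETIC_CODES["std"].stop_codons == {"TAA", "TAG", "TGA"}
        assert GENETIC_CODES["vert"].stop_codons == {"TAA", "TAG", "AGA", "AGG"}
        assert GENETIC_CODES["invert"].stop_codons == {"TAA", "TAG"}


class TestTranslationCheck:
    @pytest.mark.parametrize(
        ("seq", "code", "ok"),
        [
            ("ATGGCCATT", "invert", True),     # frame 1 stop-free
            ("ATGAGAAAA", "vert", True),       # frame 1 has AGA, frame 2 clean
            ("TAATAGTGA", "std", True),        # frame 1 all stops, frame 2 clean
            ("TAAGTAAGTAAG", "invert", False), # stop in every frame
            ("TAAGTAAGTAAG", "vert", False),
            ("TAAGTAAGTAAG", "std", False),
            ("AT", "invert", False),           # shorter than one codon
            ("A--T", "invert", False),         # degapped too short
            ("ATGNNNGCC", "invert", True),     # ambiguous codon skipped
        ],
    )
    def test_frame_scan(self, seq, code, ok):
        assert translation_check(seq, GENETIC_CODES[code]) is ok

    def test_gaps_removed_before_translation(self):
        assert translation_check("AT-GGC--CATT", GENETIC_CODES["invert"])


class TestAgctCheck:
    @pytest.mark.parametrize(
        ("seq", "ok"),
        [("ACGT", True), ("acgt", True), ("ACGTN", False),
         ("AC-GT", True), ("ACRGT", False), ("", True)],
    )
    def test_examples(self, seq, ok):
        assert agct_check(seq) is ok


# --- barcode gap ---------------------------------------------------------

class TestBarcodeGap:
    def test_two_species_with_gap(self):
        dm = p_distance_matrix(
            msa_of({
                "s1": "AAAAAAAAAA",
                "s2": "AAAAAAAAAT",   # 0.1 to s1
                "s3": "TTTTTAAAAA",   # 0.5 to s1, 0.6 to s2
            })
        )
        rows = barcode_gap_report(
            dm, {"s1": "A a", "s2": "A a", "s3": "A b"}
        )
        by_sp = {r.species: r for r in rows}
        a = by_sp["A a"]
        assert a.n == 2 and a.max_intra == pytest.approx(0.1)
        assert a.min_inter == pytest.approx(0.5)
        assert a.gap_present is True
        b = by_sp["A b"]
        assert b.max_intra is None and b.gap_present is None

    def test_identical_species_have_no_gap(self):
        dm = p_distance_matrix(
            msa_of({"s1": "ACGT", "s2": "ACGT", "s3": "ACGT", "s4": "ACGT"})
        )
        rows = barcode_gap_report(
            dm, {"s1": "A a", "s2": "A a", "s3": "A b", "s4": "A b"}
        )
        for r in rows:
            assert r.min_inter == 0 and r.max_intra == 0
            assert r.gap_present is False  # strict inequality

    def test_single_species_min_inter_missing(self):
        dm = p_distance_matrix(msa_of({"s1": "ACGT", "s2": "ACGA"}))
        (row,) = barcode_gap_report(dm, {"s1": "A a", "s2": "A a"})
        assert row.min_inter is None and row.gap_present is None

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ids = [f"s{i}" for i in range(n)]
        seqs = {
            i: "".join(rng.choice(list("ACGT-"), size=20,
                                  p=[0.22] * 4 + [0.12]))
            for i in ids
        }
        species = {i: f"A {rng.choice(['a', 'b', 'c'])}" for i in ids}
        dm = p_distance_matrix(msa_of(seqs))
        dmat = [
            [None if np.isnan(dm.d[i][j]) else dm.d[i][j] for j in range(n)]
            for i in range(n)
        ]
        expect = brute_gap_rows(ids, dmat, species)
        for row in barcode_gap_report(dm, species):
            en, emi, emn, eg = expect[row.species]
            assert row.n == en
            assert row.max_intra == (pytest.approx(emi) if emi is not None else None)
            assert row.min_inter == (pytest.approx(emn) if emn is not None else None)
            assert row.gap_present == eg


# --- full pipeline -------------------------------------------------------

class TestCleanDataset:
    def _fixture_inputs(self, **kw):
        fx = generate_fixture(FixtureSpec(**kw))
        tax = {h: (h.split("|")[2], h.split("|")[3]) for h, _ in fx.records}
        msa = msa_of({h: s for h, s in fx.records})
        return fx, tax, msa

    def test_mixed_fixture_recovers_truth(self):
        fx, tax, msa = self._fixture_inputs(seed=11)
        res = clean_dataset(msa, tax)
        assert res.flags == fx.truth.expected_flags
        assert len(res.retained) == 10

    def test_all_clean_fixture_is_identity(self):
        fx, tax, msa = self._fixture_inputs(
            seed=2, n_outliers=0, n_ambig=0, n_stop=0
        )
        res = clean_dataset(msa, tax)
        assert set(res.flags.values()) == {"-"}
        assert res.retained.ids == msa.ids

    def test_screens_off_leave_only_distance_flags(self):
        fx, tax, msa = self._fixture_inputs(seed=11)
        res = clean_dataset(
            msa, tax, CleanConfig(aa_code="off", agct_only=False)
        )
        assert set(res.flags.values()) <= {"-", "Genus_Outlier", "Species_Outlier"}
        # the planted divergent record is still caught
        outlier = next(h for h in msa.ids if "SYNO" in h)
        assert res.flags[outlier] == "Genus_Outlier"

    def test_flag_partition_is_exhaustive(self):
        fx, tax, msa = self._fixture_inputs(seed=4)
        res = clean_dataset(msa, tax)
        assert set(res.flags) == set(msa.ids)
        assert len(res.retained) + sum(
            1 for f in res.flags.values() if f != "-"
        ) == len(msa)

    def test_single_survivor_skips_distance_stages(self):
        msa = msa_of({"s1": "ACGTNACGT", "s2": "ATGGCCATT"})
        res = clean_dataset(
            msa, {"s1": ("A", "a"), "s2": ("A", "a")}
        )
        assert res.flags["s1"] == "non_AGCT"
        assert res.distance_matrix is None and res.gap_rows == []

    def test_unplaceable_record_flagged_genus(self):
        rows = {
            "s1": "ACGTACGTACGT", "s2": "ACGAACGTACGT",
            "s3": "ACGTACGAACGT", "s4": "ACGTACGTACGA",
            "un": "------------",
        }
        res = clean_dataset(
            msa_of(rows),
            {sid: ("A", "a") for sid in rows},
            CleanConfig(aa_code="off", agct_only=False),
        )
        assert res.flags["un"] == "Genus_Outlier"
        assert all(res.flags[s] == "-" for s in ("s1", "s2", "s3", "s4"))


class TestCleanFile:
    def test_three_outputs_written(self, tmp_path):
        fx = generate_fixture(FixtureSpec(seed=9))
        fasta = tmp_path / "Simulomys_COI-5P.fas"
        with open(fasta, "w") as fh:
            for h, s in fx.records:
                fh.write(f">{h}\n{s}\n")
        res = clean_file(fasta)
        stem = "Simulomys_COI-5P"
        for suffix in ("_dist_table.dat", "_data_table.dat", "_no_outlier.fas"):
            assert (tmp_path / f"{stem}{suffix}").is_file()
        data = (tmp_path / f"{stem}_data_table.dat").read_text().splitlines()
        assert data[0] == "id\tgenus\tspecies\tflag"
        assert len(data) == 1 + len(fx.records)
        kept = (tmp_path / f"{stem}_no_outlier.fas").read_text().count(">")
        assert kept == len(res.retained)
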