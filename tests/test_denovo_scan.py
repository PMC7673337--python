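"""Approach II: ab initio perfect interspaced peptide repeats."""

import numpy as np
import pytest

from _oracles import spaced_repeats_bruteforce
from spurscan.denovo_scan import find_spaced_repeats, scan_database_ab_initio
from spurscan.errors import InputError
from spurscan.model import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def as_tuples(reports):
    return [(r.unit, r.occurrence_starts) for r in reports]


class TestFindSpacedRepeats:
    def test_worked_example_named_unit(self):
        seq = "M" + "GRGLFNKKT" + "DEDEDEDEDE" + "GRGLFNKKT" + "K"
        got = find_spaced_repeats(seq)
        assert len(got) == 1
        assert got[0].unit == "GRGLFNKKT"
        assert got[0].occurrence_starts == (1, 20)
        assert got[0].spacer_lengths == (10,)

    def test_degenerate_zinc_ribbon_like_motif_not_reported(self):
        # copies differ at the variable positions, and the conserved unit
        # is 6 aa, below the unit-length floor
        seq = "M" + "FCAACG" + "W" * 15 + "FCTTCG" + "K"
        assert find_spaced_repeats(seq) == []

    def test_tandem_and_homopolymer_runs_excluded(self):
        assert find_spaced_repeats("A" * 22) == []
        assert find_spaced_repeats("MKV" + "WLDPTEH" * 4 + "GSR") == []

    @pytest.mark.parametrize(
        "unit_len,expected", [(6, 0), (7, 1), (20, 1), (21, 0)]
    )
    def test_unit_length_bounds(self, unit_len, expected):
        rng = np.random.default_rng(unit_len)
        unit = "".join(AA[i] for i in rng.integers(0, 20, size=unit_len))
        spacer = "".join(AA[i] for i in rng.integers(0, 20, size=10))
        seq = "MY" + unit + spacer + unit + "WE"
        got = [r for r in find_spaced_repeats(seq) if r.unit == unit]
        assert len(got) == expected

    @pytest.mark.parametrize("gap,expected", [(6, 0), (7, 1), (20, 1), (21, 0)])
    def test_spacer_length_bounds(self, gap, expected):
        unit = "WLDPTEHKV"
        spacer = "ACDEFGHIKLMNPQRSTVACD"[:gap]
        seq = "M" + unit + spacer + unit + "G"
        got = [r for r in find_spaced_repeats(seq) if r.unit == unit]
        assert len(got) == expected

    def test_x_never_matches_x(self):
        seq = "M" + "WLDXTEHKV" + "A" * 10 + "WLDXTEHKV" + "G"
        assert all("X" not in r.unit for r in find_spaced_repeats(seq))
        assert find_spaced_repeats(seq) == []

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(InputError):
            find_spaced_repeats("")

    def test_inverted_bounds_are_an_error(self):
        with pytest.raises(InputError):
            find_spaced_repeats("MAAA", unit_min=10, unit_max=7)


def random_sequences(n, seed, min_len=20, max_len=90, max_alpha=20):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        length = int(rng.integers(min_len, max_len))
        alpha = AA[: int(rng.integers(2, max_alpha))]
        yield "".join(alpha[i] for i in rng.integers(0, len(alpha), size=length))


def adversarial_sequences():
    rng = np.random.default_rng(2024)
    unit = "WLDPTEHKV"
    cases = [
        "A" * 300,  # homopolymer
        ("AB" * 150),  # period two
        ("ABCDEFG" * 40),  # tandem long
        "M" + unit + "A" * 6 + unit,  # spacer 6: below range
        "M" + unit + "A" * 7 + unit,  # spacer 7: bound
        "M" + unit + "A" * 20 + unit,  # spacer 20: bound
        "M" + unit + "A" * 21 + unit,  # spacer 21: above range
        # nested: a long repeat containing a shorter one
        "M" + "KV" + unit + "KV" + "C" * 9 + "KV" + unit + "KV" + "W",
        # three copies, mixed in-range/out-of-range gaps
        "M" + unit + "A" * 10 + unit + "C" * 25 + unit,
        # overlapping-occurrence stress: unit with internal period
        "M" + "ABABABA" + "C" * 8 + "ABABABA" + "D",
    ]
    for _ in range(40):
        # planted pair with random unit/spacer at the range boundaries
        ulen = int(rng.integers(6, 22))
        gap = int(rng.integers(6, 22))
        u = "".join(AA[i] for i in rng.integers(0, 6, size=ulen))
        sp = "".join(AA[i] for i in rng.integers(0, 6, size=gap))
        cases.append("MM" + u + sp + u + "KK")
    return cases


def test_matches_bruteforce_oracle_on_random_and_adversarial_strings():
    n_checked = 0
    for seq in list(random_sequences(600, seed=31)) + adversarial_sequences():
        for dedupe in (True, False):
            got = as_tuples(
                find_spaced_repeats(seq, dedupe=dedupe)
            )
            expected = spaced_repeats_bruteforce(seq, dedupe=dedupe)
            assert got == expected, (seq, dedupe)
        n_checked += 1
    assert n_checked >= 600


def test_matches_oracle_with_nondefault_bounds():
    for seq in random_sequences(150, seed=32, max_alpha=5):
        got = as_tuples(find_spaced_repeats(seq, 5, 9, 4, 12))
        assert got == spaced_repeats_bruteforce(seq, 5, 9, 4, 12)


def test_reversal_invariance_up_to_mirroring():
    checked_deduped = 0
    for seq in list(random_sequences(400, seed=99, max_alpha=6)) + adversarial_sequences():
        fwd = find_spaced_repeats(seq, dedupe=False)
        rev = find_spaced_repeats(seq[::-1], dedupe=False)
        n = len(seq)
        mirrored = sorted(
            (
                r.unit[::-1],
                tuple(sorted(n - p - len(r.unit) for p in r.occurrence_starts)),
            )
            for r in rev
        )
        assert sorted((r.unit, r.occurrence_starts) for r in fwd) == mirrored
        # when no report was suppressed by overlap-dedup, the deduplicated
        # output must mirror as well
        fwd_d = find_spaced_repeats(seq, dedupe=True)
        rev_d = find_spaced_repeats(seq[::-1], dedupe=True)
        if len(fwd_d) == len(fwd) and len(rev_d) == len(rev):
            mirrored_d = sorted(
                (
                    r.unit[::-1],
                    tuple(sorted(n - p - len(r.unit) for p in r.occurrence_starts)),
                )
                for r in rev_d
            )
            assert sorted((r.unit, r.occurrence_starts) for r in fwd_d) == mirrored_d
            checked_deduped += 1
    assert checked_deduped > 100


def test_output_order_is_leftmost_then_longest():
    unit_a, unit_b = "WLDPTEHKV", "ACDEFGHIKLMN"
    seq = "M" + unit_a + "G" * 10 + unit_a + "Y" * 30 + unit_b + "G" * 12 + unit_b
    got = find_spaced_repeats(seq)
    starts = [r.occurrence_starts[0] for r in got]
    assert starts == sorted(starts)
    assert {r.unit for r in got} == {unit_a, unit_b}


class TestScanDatabaseAbInitio:
    def test_subset_of_approach_one_on_exact_fixtures(self, small_fixture):
        import pandas as pd

        from spurscan.io import read_proteins_fasta, read_repeats_fasta
        from spurscan.repeat_scan import scan_database
        from spurscan.translation import build_peptide_index

        d = small_fixture["dir"]
        index = build_peptide_index(read_repeats_fasta(d / "repeats.fasta"))
        cands1 = scan_database(read_proteins_fasta(d / "proteins.fasta"), index)
        flagged2 = {
            c.accession
            for c in scan_database_ab_initio(
                read_proteins_fasta(d / "proteins.fasta")
            )
        }
        # the ab initio scan has a 7 aa unit floor, so the subset property
        # covers approach-I candidates whose matched peptides are in range;
        # 6 aa frame peptides of 20 bp repeats are approach I's edge alone
        flagged1_in_range = {
            c.accession
            for c in cands1
            if all(len(m.peptide) >= 7 for m in c.matches)
        }
        assert flagged1_in_range <= flagged2
        # overlap fraction is 1.0 by construction (all copies exact)
        assert len(flagged1_in_range & flagged2) / len(flagged1_in_range) == 1.0

    def test_decoys_and_boundary_units_not_recovered(self, small_fixture):
        import pandas as pd

        d = small_fixture["dir"]
        from spurscan.io import read_proteins_fasta

        flagged = {
            c.accession
            for c in scan_database_ab_initio(
                read_proteins_fasta(d / "proteins.fasta")
            )
        }
        truth = pd.read_csv(d / "truth.tsv", sep="\t")
        decoys = set(
            truth[~truth.planted_class.str.startswith("spurious")].accession
        )
        assert flagged & decoys == set()

    def test_duplicate_accessions_are_an_error(self):
        with pytest.raises(InputError, match="duplicate"):
            scan_database_ab_initio(
                [
                    ProteinRecord("P1", "MAAAA"),
                    ProteinRecord("P1", "MCCCC"),
                ]
            )
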