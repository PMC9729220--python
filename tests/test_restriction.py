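"""Double-strand-aware site finding and digestion, against a brute-force oracle."""

from collections import Counter

import numpy as np
import pytest

import lesionbypass as lb
from lesionbypass.constructs import LEFT_FLANK, RIGHT_FLANK

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _rc(s):
    return "".join(COMP[b] for b in reversed(s))


class TestBuiltins:
    def test_recognitions_and_offsets(self):
        by_name = {e.name: e for e in lb.builtin_enzymes()}
        assert lb.lookup("PstI").recognition == "CTGCAG"
        assert lb.lookup("EcoRI").recognition == "GAATTC"
        assert by_name["HindIII"].recognition == "AAGCTT"
        assert by_name["EcoRI"].cut_after_top == 1
        assert by_name["HindIII"].cut_after_top == 1
        assert by_name["PstI"].cut_after_top == 5
        for e in by_name.values():
            assert e.is_palindromic
            assert e.cut_after_bottom == e.cut_after_top

    def test_enzyme_table_loader(self, tmp_path):
        p = tmp_path / "enzymes.txt"
        p.write_text("# name recognition cut\nBamHI GGATCC 1\nSphI GCATGC 5\n")
        loaded = lb.load_enzyme_table(p)
        assert [(e.name, e.recognition, e.cut_after_top) for e in loaded] == [
            ("BamHI", "GGATCC", 1),
            ("SphI", "GCATGC", 5),
        ]


class TestFindSites:
    def test_restored_progeny_has_one_psti_site(self, constructs_g):
        std = constructs_g[-1]
        d = lb.progeny_amplicon(std)
        assert len(lb.find_sites(d, lb.PSTI)) == 1

    def test_com20_progeny_has_no_psti_site(self):
        # the complement strand's product reads CTGCAC at the site region
        assert lb.find_sites(lb.com20_amplicon(), lb.PSTI) == []

    def test_mismatch_inside_site_abolishes_it(self, constructs_g):
        # original STD/COM20 hetero-duplex carries the C:C mismatch in-site
        std = constructs_g[-1]
        assert lb.find_sites(lb.recombinant_amplicon(std), lb.PSTI) == []
        # same 6-mer on the top strand alone would qualify
        assert lb.find_sites(lb.progeny_amplicon(std), lb.PSTI) != []

    def test_unpaired_site_not_reported(self, std_strand, com20_strand):
        # EcoRI's GAATTC half lives in the single-stranded AATT overhang region
        d = lb.anneal(std_strand, com20_strand)
        top = lb.ChiralStrand.from_str("G" + lb.STD_SEQ, "ext")
        assert "GAATTC" in top.seq
        ext = lb.anneal(top, com20_strand)
        assert lb.find_sites(ext, lb.ECORI) == []

    def test_chirality_block_flag(self):
        # a mismatch-free duplex with an L sugar inside the PstI site
        top = lb.ChiralStrand.from_str(
            LEFT_FLANK + lb.STD_SEQ + RIGHT_FLANK, "t", l_positions=(len(LEFT_FLANK) + 10,)
        )
        d = lb.perfect_duplex(top)
        assert len(lb.find_sites(d, lb.PSTI)) == 1  # default: chirality ignored
        assert lb.find_sites(d, lb.PSTI, chirality_blocks=True) == []


class TestDigest:
    def test_20mer_product_sequence(self, constructs_g):
        d = lb.progeny_amplicon(constructs_g[-1])
        assert len(d.top) == 70
        frags = lb.digest(d, [lb.PSTI, lb.HINDIII])
        twenties = [f for f in frags if f.length == 20]
        assert [f.sequence.seq for f in twenties] == ["AGCTTCAGTGCTAGCCTGCA"]

    def test_ecori_hindiii_releases_24mer_insert(self, constructs_g):
        for c in constructs_g:
            frags = lb.digest(lb.recombinant_amplicon(c), [lb.ECORI, lb.HINDIII])
            seqs = {f.sequence.seq for f in frags if f.length == 24}
            assert c.insert.top.seq in seqs
            assert lb.COM20_SEQ in seqs  # the complement strand's 24-mer

    def test_no_sites_returns_intact_strands(self):
        top = lb.ChiralStrand.from_str("ACGTACGTACGTACGT", "t")
        frags = lb.digest(lb.perfect_duplex(top), lb.builtin_enzymes())
        assert sorted(f.length for f in frags) == [16, 16]

    @pytest.mark.parametrize("seed", range(5))
    def test_length_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 200))
        top = "".join(rng.choice(list("ACGT"), size=n))
        # sprinkle a few enzyme sites to ensure cutting happens sometimes
        for site in ("GAATTC", "CTGCAG", "AAGCTT"):
            pos = int(rng.integers(0, n - 6))
            top = top[:pos] + site + top[pos + 6 :]
        d = lb.perfect_duplex(lb.ChiralStrand.from_str(top, "t"))
        frags = lb.digest(d, lb.builtin_enzymes())
        per_strand = Counter()
        for f in frags:
            per_strand[f.origin] += f.length
        assert per_strand[d.top.name] == len(d.top)
        assert per_strand[d.bottom.name] == len(d.bottom)

    def test_orientation_symmetry(self, constructs_g):
        d = lb.progeny_amplicon(constructs_g[-1])
        flipped = d.flipped()
        a = sorted(f.length for f in lb.digest(d, lb.builtin_enzymes()))
        b = sorted(f.length for f in lb.digest(flipped, lb.builtin_enzymes()))
        assert a == b


def oracle_fragment_lengths(top, bottom, enzymes):
    """Brute-force reference digest of a blunt duplex given as two strings.

    Tests every hexamer window on both strands for a fully Watson-Crick
    paired recognition match and splits each strand at the enzyme's offset.
    Entirely string-based and independent of the package's duplex machinery.
    """
    n = len(top)
    assert len(bottom) == n

    def aligned_ok(strand, other, i, k):
        # window [i, i+k) of `strand`; `other` runs antiparallel
        return all(other[n - 1 - (i + j)] == COMP[strand[i + j]] for j in range(k))

    top_cuts, bottom_cuts = set(), set()
    for e in enzymes:
        k = len(e.recognition)
        for i in range(n - k + 1):
            if top[i : i + k] == e.recognition and aligned_ok(top, bottom, i, k):
                top_cuts.add(i + e.cut_after_top)
                bottom_cuts.add(n - i - k + e.cut_after_bottom)
            if bottom[i : i + k] == e.recognition and aligned_ok(bottom, top, i, k):
                bottom_cuts.add(i + e.cut_after_top)
                top_cuts.add(n - i - k + e.cut_after_bottom)

    def lengths(cuts):
        bounds = sorted(c for c in cuts if 0 < c < n)
        return [b - a for a, b in zip([0] + bounds, bounds + [n])]

    return sorted(lengths(top_cuts) + lengths(bottom_cuts))


@pytest.mark.parametrize("seed", range(20))
def test_digest_agrees_with_brute_force_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    n = int(rng.integers(50, 200))
    top = "".join(rng.choice(list("ACGT"), size=n))
    for site in ("GAATTC", "CTGCAG", "AAGCTT", "CTGCAG"):
        pos = int(rng.integers(0, n - 6))
        top = top[:pos] + site + top[pos + 6 :]
    bottom = _rc(top)
    # randomly mutate a few bottom positions to create mismatches
    for _ in range(int(rng.integers(0, 4))):
        pos = int(rng.integers(0, n))
        bottom = bottom[:pos] + rng.choice(list("ACGT")) + bottom[pos + 1 :]
    d = lb.Duplex(
        top=lb.ChiralStrand.from_str(top, "t"),
        bottom=lb.ChiralStrand.from_str(bottom, "b"),
    )
    got = sorted(f.length for f in lb.digest(d, lb.builtin_enzymes()))
    assert got == oracle_fragment_lengths(top, bottom, lb.builtin_enzymes())
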