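"""Double-strand-aware restriction site finding and in-silico digestion.

The assay reads out replication products through three type II enzymes with
palindromic 6-bp recognition sites: EcoRI (G^AATTC), HindIII (A^AGCTT) and
PstI (CTGCA^G).  Site recognition here is strict double-strand recognition:
a site counts only if all six positions lie in the paired region of the
duplex and none of them is a base mismatch.  This all-or-none rule is what
lets a single C:C mismatch next to the PstI site distinguish strand origin,
and what makes the CTGCAC progeny of the complement strand uncuttable.

Digestion is simultaneous and complete (no partial digests), and fragments
are reported as single strands with their own lengths, matching what a
denaturing polyacrylamide gel resolves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seq_core import (
    ChiralStrand,
    Duplex,
    InputError,
    MATCH,
    DNA_ALPHABET,
    revcomp,
)


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme.

    ``cut_after_top`` is the number of bases of the recognition site that lie
    5' of the cut on the top strand; ``cut_after_bottom`` is the analogous
    offset counted from the bottom strand's 5' side of the site.  For a
    palindromic site the two are equal, which is the default.
    """

    name: str
    recognition: str
    cut_after_top: int
    cut_after_bottom: int | None = None

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - DNA_ALPHABET:
            raise InputError(f"{self.name}: recognition must be non-empty A/C/G/T")
        k = len(self.recognition)
        if not 0 <= self.cut_after_top <= k:
            raise InputError(f"{self.name}: cut_after_top must be in [0, {k}]")
        if self.cut_after_bottom is None:
            object.__setattr__(self, "cut_after_bottom", self.cut_after_top)
        if not 0 <= self.cut_after_bottom <= k:  # type: ignore[operator]
            raise InputError(f"{self.name}: cut_after_bottom must be in [0, {k}]")

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rc = "".join(comp[b] for b in reversed(self.recognition))
        return rc == self.recognition


ECORI = Enzyme("EcoRI", "GAATTC", 1)
HINDIII = Enzyme("HindIII", "AAGCTT", 1)
PSTI = Enzyme("PstI", "CTGCAG", 5)

_BUILTINS = {e.name: e for e in (ECORI, HINDIII, PSTI)}


def builtin_enzymes() -> list[Enzyme]:
    """The three enzymes used by the assay, with standard cut offsets."""
    return [ECORI, HINDIII, PSTI]


def lookup(name: str) -> Enzyme:
    try:
        return _BUILTINS[name]
    except KeyError:
        raise InputError(
            f"unknown enzyme {name!r}; built-ins: {sorted(_BUILTINS)}"
        ) from None


def load_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Load enzyme definitions from a flat text table.

    Whitespace-separated columns: name, recognition, cut_after_top.  Lines
    starting with ``#`` are comments.  Lets users extend beyond the three
    built-ins.
    """
    enzymes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise InputError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        name, recognition, cut = parts
        try:
            enzymes.append(Enzyme(name, recognition.upper(), int(cut)))
        except ValueError:
            raise InputError(f"{path}:{lineno}: cut_after_top must be an integer") from None
    return enzymes


@dataclass(frozen=True)
class Fragment:
    """A single-strand digestion product, as resolved on a denaturing gel."""

    sequence: ChiralStrand
    origin: str  # parent strand label

    @property
    def length(self) -> int:
        return len(self.sequence)


def find_sites(
    d: Duplex, e: Enzyme, chirality_blocks: bool = False
) -> list[int]:
    """Top-strand 1-based start positions of cleavable recognition sites.

    A position qualifies only if (a) the top strand matches the recognition
    sequence there, (b) every position of the site lies in the paired region,
    and (c) all pairing flags across the site are matches.  With
    ``chirality_blocks`` an L sugar anywhere in the site additionally blocks
    cutting (off by default: the assay digests PCR products, which are all-D).
    """
    k = e.site_length
    top = d.top.seq
    sites = []
    for s in range(1, len(top) - k + 2):
        if top[s - 1 : s - 1 + k] != e.recognition:
            continue
        ok = True
        for pos in range(s, s + k):
            if d.pairing_at(pos) != MATCH:
                ok = False
                break
            if chirality_blocks:
                bpos = d.bottom_pos_at_col(d.col_of_top(pos))
                if (
                    d.top.chirality_at(pos) == "L"
                    or (bpos is not None and d.bottom.chirality_at(bpos) == "L")
                ):
                    ok = False
                    break
        if ok:
            sites.append(s)
    return sites


def _split_strand(strand: ChiralStrand, cuts_after: Iterable[int]) -> list[ChiralStrand]:
    """Split at each 1-based 'cut after position p' bond; interior cuts only."""
    bounds = sorted({c for c in cuts_after if 1 <= c < len(strand)})
    frags = []
    start = 1
    for c in bounds:
        frags.append(strand.slice(start, c))
        start = c + 1
    frags.append(strand.slice(start, len(strand)))
    return frags


def digest(
    d: Duplex, enzymes: Sequence[Enzyme], chirality_blocks: bool = False
) -> list[Fragment]:
    """Cut at all sites of all enzymes simultaneously; return single strands.

    Each strand is cut independently at its own offset within every site.
    Per strand, the fragment lengths always sum to the parent strand length.
    A duplex with no sites comes back as its two intact strands.
    """
    top_cuts: set[int] = set()
    bottom_cuts: set[int] = set()
    for e in enzymes:
        k = e.site_length
        for s in find_sites(d, e, chirality_blocks=chirality_blocks):
            top_cuts.add(s + e.cut_after_top - 1)
            # bottom cut: cut_after_bottom bases from the bottom strand's 5'
            # side of the site, i.e. from the rightmost site column.
            right_col = d.col_of_top(s + k - 1)
            cut_col = right_col - e.cut_after_bottom  # bond between cut_col, cut_col+1
            bpos_right = d.bottom_pos_at_col(cut_col + 1)
            if bpos_right is not None:
                bottom_cuts.add(bpos_right)
    frags = [
        Fragment(sequence=piece, origin=d.top.name)
        for piece in _split_strand(d.top, top_cuts)
    ]
    frags += [
        Fragment(sequence=piece, origin=d.bottom.name)
        for piece in _split_strand(d.bottom, bottom_cuts)
    ]
    return frags
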