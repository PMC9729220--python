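"""Chirality-aware sequence and duplex primitives.

The assay studied here works with short synthetic oligonucleotides in which a
single template position may be an L-deoxyribonucleoside — the mirror-image
(levorotatory) enantiomer of the natural D-sugar nucleoside.  Chirality does
not change Watson–Crick base identity, so an L base can still be written with
its normal letter and can still "pair" in a duplex; the flag only marks the
lesion for the replication simulator downstream.  These primitives therefore
track chirality per position while keeping all complementarity bookkeeping
purely base-wise.

Coordinates are 1-based and inclusive, along each strand 5'→3'.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
CHIRALITIES = frozenset("DL")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement_base(base: str) -> str:
    """Watson–Crick complement of a single base letter."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise InputError(f"not a DNA base: {base!r}") from None


# ---------------------------------------------------------------------------
# Errors shared across the package
# ---------------------------------------------------------------------------


class LesionBypassError(Exception):
    """Base class for all errors raised by this package."""


class InputError(LesionBypassError):
    """Malformed sequence or file input."""


class AnnealingError(LesionBypassError):
    """No duplex alignment meets the match threshold."""


class AmbiguityError(AnnealingError):
    """More than one equally good annealing alignment."""


class DesignError(LesionBypassError):
    """A construct set violates the decode design (non-unique restoration)."""


class ParameterError(LesionBypassError):
    """Invalid simulation parameters."""


class ConfigError(LesionBypassError):
    """Invalid scenario configuration; the message names the field."""


class DataError(LesionBypassError):
    """Band table missing required rows (e.g. failed-construction 24mer)."""


class ControlError(DataError):
    """The STD control sample is missing or unusable."""


# ---------------------------------------------------------------------------
# Strands
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChiralNucleotide:
    """One nucleotide with a sugar-chirality flag (``D`` natural, ``L`` lesion)."""

    base: str
    chirality: str = "D"

    def __post_init__(self) -> None:
        if self.base not in DNA_ALPHABET:
            raise InputError(f"base must be one of A/C/G/T, got {self.base!r}")
        if self.chirality not in CHIRALITIES:
            raise InputError(f"chirality must be D or L, got {self.chirality!r}")

    def __str__(self) -> str:  # G^L style, matching oligo-table notation
        return self.base + ("^L" if self.chirality == "L" else "")


@dataclass(frozen=True)
class ChiralStrand:
    """A 5'→3' oligonucleotide with per-position chirality.

    ``l_positions`` lists the 1-based positions carrying an L sugar.  Assay
    strands carry at most one, but that is a construct-level rule enforced in
    :mod:`lesionbypass.constructs`, not here.
    """

    name: str
    nucleotides: tuple[ChiralNucleotide, ...]

    def __post_init__(self) -> None:
        if len(self.nucleotides) < 1:
            raise InputError(f"strand {self.name!r} must have length >= 1")

    @classmethod
    def from_str(
        cls, seq: str, name: str = "", l_positions: Iterable[int] = ()
    ) -> "ChiralStrand":
        lset = set(l_positions)
        bad = [p for p in lset if not 1 <= p <= len(seq)]
        if bad:
            raise InputError(f"L positions {bad} outside strand of length {len(seq)}")
        nts = tuple(
            ChiralNucleotide(b, "L" if i + 1 in lset else "D")
            for i, b in enumerate(seq.upper())
        )
        return cls(name=name, nucleotides=nts)

    @property
    def seq(self) -> str:
        """Plain base letters (the D-analog spelling used in FASTA output)."""
        return "".join(nt.base for nt in self.nucleotides)

    @property
    def l_positions(self) -> tuple[int, ...]:
        return tuple(
            i + 1 for i, nt in enumerate(self.nucleotides) if nt.chirality == "L"
        )

    def __len__(self) -> int:
        return len(self.nucleotides)

    def base_at(self, pos: int) -> str:
        """Base letter at 1-based position ``pos``."""
        return self.nucleotides[pos - 1].base

    def chirality_at(self, pos: int) -> str:
        return self.nucleotides[pos - 1].chirality

    def slice(self, start: int, end: int, name: str | None = None) -> "ChiralStrand":
        """Sub-strand over 1-based inclusive ``[start, end]``."""
        if not (1 <= start <= end <= len(self)):
            raise InputError(f"slice [{start},{end}] outside strand of length {len(self)}")
        return ChiralStrand(
            name=name if name is not None else self.name,
            nucleotides=self.nucleotides[start - 1 : end],
        )


def revcomp(s: ChiralStrand, name: str | None = None) -> ChiralStrand:
    """Reverse complement; chirality flags travel with their positions."""
    nts = tuple(
        ChiralNucleotide(complement_base(nt.base), nt.chirality)
        for nt in reversed(s.nucleotides)
    )
    return ChiralStrand(name=name if name is not None else s.name + "_rc", nucleotides=nts)


# ---------------------------------------------------------------------------
# Duplexes
# ---------------------------------------------------------------------------

MATCH = "match"
MISMATCH = "mismatch"


@dataclass(frozen=True)
class Duplex:
    """Two antiparallel strands in a fixed ungapped alignment.

    The alignment is laid out on columns numbered 1..W left to right, with the
    top strand written 5'→3' and the bottom strand 3'→5'.  ``top_offset`` and
    ``bottom_offset`` give the number of columns to the left of the top
    strand's 5' end and the bottom strand's 3' end respectively; at least one
    of them is zero.  Overhangs and the per-position match/mismatch map are
    derived from this geometry.
    """

    top: ChiralStrand
    bottom: ChiralStrand
    top_offset: int = 0
    bottom_offset: int = 0

    def __post_init__(self) -> None:
        if self.top_offset < 0 or self.bottom_offset < 0:
            raise InputError("duplex offsets must be >= 0")
        if min(self.top_offset, self.bottom_offset) != 0:
            raise InputError("at least one duplex offset must be 0")
        if self.paired_length < 1:
            raise InputError("duplex paired region must be >= 1 nt")

    # -- geometry -----------------------------------------------------------

    @property
    def width(self) -> int:
        return max(self.top_offset + len(self.top), self.bottom_offset + len(self.bottom))

    @property
    def _overlap(self) -> tuple[int, int]:
        lo = max(self.top_offset, self.bottom_offset) + 1
        hi = min(self.top_offset + len(self.top), self.bottom_offset + len(self.bottom))
        return lo, hi

    @property
    def paired_length(self) -> int:
        lo, hi = self._overlap
        return hi - lo + 1

    @property
    def top_5p_overhang(self) -> int:
        """Top-strand 5' bases extending past the bottom strand's 3' end."""
        return max(0, self.bottom_offset - self.top_offset)

    @property
    def bottom_5p_overhang(self) -> int:
        """Bottom-strand 5' bases extending past the top strand's 3' end."""
        return max(
            0,
            (self.bottom_offset + len(self.bottom)) - (self.top_offset + len(self.top)),
        )

    # -- column/position maps ----------------------------------------------

    def top_pos_at_col(self, col: int) -> int | None:
        pos = col - self.top_offset
        return pos if 1 <= pos <= len(self.top) else None

    def bottom_pos_at_col(self, col: int) -> int | None:
        """Bottom-strand 5'→3' position occupying alignment column ``col``."""
        pos = len(self.bottom) - (col - self.bottom_offset) + 1
        return pos if 1 <= pos <= len(self.bottom) else None

    def col_of_top(self, pos: int) -> int:
        return self.top_offset + pos

    def is_paired(self, top_pos: int) -> bool:
        return self.bottom_pos_at_col(self.col_of_top(top_pos)) is not None

    def pairing_at(self, top_pos: int) -> str | None:
        """MATCH/MISMATCH flag at a top-strand position, None if unpaired."""
        bpos = self.bottom_pos_at_col(self.col_of_top(top_pos))
        if bpos is None:
            return None
        t = self.top.base_at(top_pos)
        b = self.bottom.base_at(bpos)
        return MATCH if b == complement_base(t) else MISMATCH

    @property
    def pairing(self) -> tuple[tuple[int, int, str], ...]:
        """(top_pos, bottom_pos, flag) for every aligned (paired) column."""
        out = []
        lo, hi = self._overlap
        for col in range(lo, hi + 1):
            tpos = self.top_pos_at_col(col)
            bpos = self.bottom_pos_at_col(col)
            assert tpos is not None and bpos is not None
            out.append((tpos, bpos, self.pairing_at(tpos)))
        return tuple(out)

    @property
    def mismatch_positions(self) -> tuple[int, ...]:
        """Top-strand positions flagged as base mismatches."""
        return tuple(t for t, _, flag in self.pairing if flag == MISMATCH)

    def flipped(self) -> "Duplex":
        """The same molecule viewed with top and bottom strands swapped."""
        w = self.width
        new_top_off = w - (self.bottom_offset + len(self.bottom))
        new_bot_off = w - (self.top_offset + len(self.top))
        return Duplex(self.bottom, self.top, new_top_off, new_bot_off)


def perfect_duplex(top: ChiralStrand) -> Duplex:
    """Blunt duplex of a strand with its exact full-length complement."""
    return Duplex(top=top, bottom=revcomp(top), top_offset=0, bottom_offset=0)


def anneal(top: ChiralStrand, bottom: ChiralStrand, min_matches: int = 12) -> Duplex:
    """Anneal two strands by ungapped sliding, scored by Watson–Crick matches.

    Every relative shift of the (antiparallel) bottom strand against the top
    strand is scored by the number of complementary aligned positions; the
    unique best alignment is returned provided it reaches ``min_matches``.
    The default threshold of 12 suits assay duplexes sharing a 20-bp core.

    Raises
    ------
    AnnealingError
        if no shift reaches ``min_matches`` matches.
    AmbiguityError
        if two shifts tie for the best score.
    """
    t = top.seq
    b_rev = bottom.seq[::-1]  # bottom written 3'→5', parallel to top
    best_score = -1
    best_shifts: list[int] = []
    for shift in range(-(len(b_rev) - 1), len(t)):
        score = 0
        lo = max(0, shift)
        hi = min(len(t), shift + len(b_rev))
        for i in range(lo, hi):
            if b_rev[i - shift] == _COMPLEMENT[t[i]]:
                score += 1
        if score > best_score:
            best_score, best_shifts = score, [shift]
        elif score == best_score:
            best_shifts.append(shift)
    if best_score < min_matches:
        raise AnnealingError(
            f"no alignment of {top.name!r} and {bottom.name!r} reaches "
            f"{min_matches} matches (best: {best_score})"
        )
    if len(best_shifts) > 1:
        raise AmbiguityError(
            f"{len(best_shifts)} equally good alignments of {top.name!r} and "
            f"{bottom.name!r} (score {best_score})"
        )
    shift = best_shifts[0]
    return Duplex(
        top=top,
        bottom=bottom,
        top_offset=max(0, -shift),
        bottom_offset=max(0, shift),
    )


# ---------------------------------------------------------------------------
# FASTA + chirality sidecar I/O
# ---------------------------------------------------------------------------
#
# FASTA cannot carry sugar chirality, so sequences are written with the
# D-analog letters and L positions go to a sidecar TSV with columns
# strand_name / position / chirality.  Reading the pair back reconstructs the
# strands bit-exactly.

SIDECAR_COLUMNS = ("strand_name", "position", "chirality")


def write_strands_fasta(
    strands: Sequence[ChiralStrand],
    fasta_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=s.name, description="") for s in strands
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if sidecar_path is not None:
        with open(sidecar_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(SIDECAR_COLUMNS)
            for s in strands:
                for pos in s.l_positions:
                    w.writerow([s.name, pos, "L"])


def read_strands_fasta(
    fasta_path: str | Path, sidecar_path: str | Path | None = None
) -> list[ChiralStrand]:
    l_map: dict[str, set[int]] = {}
    if sidecar_path is not None:
        with open(sidecar_path, newline="") as fh:
            r = csv.DictReader(fh, delimiter="\t")
            if r.fieldnames is None or tuple(r.fieldnames) != SIDECAR_COLUMNS:
                raise InputError(
                    f"sidecar {sidecar_path} must have columns {SIDECAR_COLUMNS}"
                )
            for row in r:
                if row["chirality"] == "L":
                    l_map.setdefault(row["strand_name"], set()).add(int(row["position"]))
    strands = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise InputError(f"record {rec.id!r} has non-ACGT characters: {sorted(bad)}")
        strands.append(
            ChiralStrand.from_str(seq, name=rec.id, l_positions=l_map.get(rec.id, ()))
        )
    return strands
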