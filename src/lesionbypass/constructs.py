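"""Lesion-bearing insert design and the incorporation decode table.

The assay's trick is a set of four single-substitution variants of a control
insert (STD) whose top strand carries an intact PstI site, 5'-CTGCAG-3'.
In variant X13 the lesion (an L-deoxyribonucleoside of base X) replaces the
T at site offset 2, in X14 the G at offset 3, in X15 the C at offset 4 and
in X16 the A at offset 5.  After replication, the progeny top strand carries
the complement of whatever base was incorporated opposite the lesion, so the
PstI site is restored — and a diagnostic 20-mer released on digestion — for
exactly one incorporated nucleotide per construct.  Over the four constructs
the four detected incorporations are exactly {A, C, G, T}, one each, which is
what lets band presence decode the full incorporation spectrum.

Each lesion strand is annealed to a common complement strand (COM20) that
carries a deliberate C at the position opposite the first C of the site
(a C:C mismatch).  Progeny descending from COM20 therefore read CTGCAC at
the site and are never cut, so all 20-mer signal traces back to replication
of the lesion strand.

The construct names (13–16) are adopted verbatim from the oligo set this
models; the name→offset map {13:2, 14:3, 15:4, 16:5} is fixed by the printed
sequences, not by arithmetic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .seq_core import (
    ChiralNucleotide,
    ChiralStrand,
    DesignError,
    Duplex,
    InputError,
    complement_base,
    anneal,
    perfect_duplex,
    write_strands_fasta,
)

#: Control insert top strand; the underlined PstI site occupies positions 8-13.
STD_SEQ = "AATTCTCCTGCAGGCTAGCACTGA"
#: Common complement strand (annealed to every insert strand).
COM20_SEQ = "AGCTTCAGTGCTAGCCTGCACGAG"

SITE_START = 8  # 1-based start of CTGCAG within the insert top strand
SITE_SEQ = "CTGCAG"

#: Construct name index -> substituted offset within the 6-nt PstI site.
INDEX_TO_OFFSET = {13: 2, 14: 3, 15: 4, 16: 5}

# Synthetic amplicon flanks standing in for the (unpublished) vector context
# of the PCR product.  They regenerate the EcoRI junction (flank ends ...G,
# insert begins AATTC) and the HindIII junction (insert ends ...A, flank
# begins AGCTT), start/end with the assay's PCR primer sequences, and contain
# no other recognition site for the three assay enzymes.
LEFT_FLANK = "TTAGCTCACTCATTAGGCACCCG"
RIGHT_FLANK = "AGCTTGCGTAATAGCGAAGAGGC"

STD_NAME = "STD"


def _std_strand() -> ChiralStrand:
    return ChiralStrand.from_str(STD_SEQ, STD_NAME)


def _com20_strand() -> ChiralStrand:
    return ChiralStrand.from_str(COM20_SEQ, "COM20")


@dataclass(frozen=True)
class Construct:
    """One lesion-bearing insert (or the unmodified STD control).

    For the control, ``lesion``, ``site_offset`` and
    ``detected_incorporation`` are ``None``.
    """

    name: str
    lesion: ChiralNucleotide | None
    site_offset: int | None
    insert: Duplex
    detected_incorporation: str | None
    outcome_label: str

    @property
    def is_control(self) -> bool:
        return self.lesion is None

    @property
    def lesion_position(self) -> int | None:
        """1-based lesion position on the insert top strand."""
        if self.site_offset is None:
            return None
        return SITE_START + self.site_offset - 1


def _outcome_label(lesion_base: str, detected: str) -> str:
    progeny_base = complement_base(detected)
    if progeny_base == lesion_base:
        # correct read-through: the lesion templated its Watson-Crick partner
        return f"l-d{lesion_base} : {detected} correct pairing"
    return f"l-d{lesion_base} → {progeny_base}"


def build_constructs(lesion_base: str) -> list[Construct]:
    """The four lesion constructs X13..X16 plus the STD control.

    Each insert top strand equals STD with exactly one position (site offsets
    2-5) replaced by the lesion base, flagged L, annealed to COM20.
    """
    if lesion_base not in "ACGT" or len(lesion_base) != 1:
        raise InputError(f"lesion base must be one of A/C/G/T, got {lesion_base!r}")
    com20 = _com20_strand()
    out = []
    for idx in sorted(INDEX_TO_OFFSET):
        offset = INDEX_TO_OFFSET[idx]
        pos = SITE_START + offset - 1
        name = f"{lesion_base}{idx}"
        seq = STD_SEQ[: pos - 1] + lesion_base + STD_SEQ[pos:]
        strand = ChiralStrand.from_str(seq, name, l_positions=(pos,))
        detected = complement_base(STD_SEQ[pos - 1])
        out.append(
            Construct(
                name=name,
                lesion=ChiralNucleotide(lesion_base, "L"),
                site_offset=offset,
                insert=anneal(strand, com20),
                detected_incorporation=detected,
                outcome_label=_outcome_label(lesion_base, detected),
            )
        )
    out.append(
        Construct(
            name=STD_NAME,
            lesion=None,
            site_offset=None,
            insert=anneal(_std_strand(), com20),
            detected_incorporation=None,
            outcome_label="control",
        )
    )
    return out


def predicted_restoration(c: Construct, incorporated: str) -> bool:
    """Does incorporating ``incorporated`` opposite the lesion restore the site?

    True iff replacing the lesion position of the progeny top strand by the
    complement of the incorporated base recreates 5'-CTGCAG-3'.  The STD
    control always restores (it never lost the site).
    """
    if incorporated not in "ACGT":
        raise InputError(f"incorporated base must be A/C/G/T, got {incorporated!r}")
    if c.is_control:
        return True
    pos = c.lesion_position
    assert pos is not None
    top = c.insert.top.seq
    progeny = top[: pos - 1] + complement_base(incorporated) + top[pos:]
    return progeny[SITE_START - 1 : SITE_START - 1 + 6] == SITE_SEQ


@dataclass(frozen=True)
class DecodeTable:
    """Map from construct name to (detected incorporation, outcome label)."""

    lesion: str
    entries: Mapping[str, tuple[str, str]]

    def detected(self, name: str) -> str:
        return self.entries[name][0]

    def label(self, name: str) -> str:
        return self.entries[name][1]

    @property
    def construct_names(self) -> tuple[str, ...]:
        return tuple(self.entries)


def decode_table(lesion_base: str) -> DecodeTable:
    """Build and verify the decode table for one lesion identity.

    Verifies by enumeration that every construct has exactly one restoring
    incorporation and that over the four constructs the detected bases are
    exactly {A, C, G, T} (injectivity), raising :class:`DesignError` otherwise.
    """
    constructs = [c for c in build_constructs(lesion_base) if not c.is_control]
    entries: dict[str, tuple[str, str]] = {}
    for c in constructs:
        restoring = [b for b in "ACGT" if predicted_restoration(c, b)]
        if len(restoring) != 1:
            raise DesignError(
                f"construct {c.name}: {len(restoring)} restoring incorporations "
                f"({restoring}); expected exactly 1"
            )
        entries[c.name] = (restoring[0], _outcome_label(lesion_base, restoring[0]))
    detected = sorted(d for d, _ in entries.values())
    if detected != ["A", "C", "G", "T"]:
        raise DesignError(
            f"decode table for lesion {lesion_base} is not injective: {entries}"
        )
    return DecodeTable(lesion=lesion_base, entries=entries)


# ---------------------------------------------------------------------------
# Amplicon builders (the PCR-product duplexes the digestion stage sees)
# ---------------------------------------------------------------------------

INTACT = "intact"  # progeny-species key for the unmodified control product


def progeny_top_insert(c: Construct, species: str) -> str:
    """Insert portion of the progeny top strand for one progeny species.

    ``species`` is the progeny base at the lesion position ("A"/"C"/"G"/"T"),
    ``"intact"`` for the control product, or ``"ins"``/``"del"`` for a
    one-base insertion/deletion at the lesion.
    """
    base_seq = STD_SEQ if c.is_control else c.insert.top.seq
    if species == INTACT:
        return base_seq
    pos = c.lesion_position
    if pos is None:
        raise InputError(f"species {species!r} undefined for the control construct")
    if species in "ACGT" and len(species) == 1:
        return base_seq[: pos - 1] + species + base_seq[pos:]
    if species == "del":
        return base_seq[: pos - 1] + base_seq[pos:]
    if species == "ins":
        ref = STD_SEQ[pos - 1]
        return base_seq[: pos - 1] + ref + ref + base_seq[pos:]
    raise InputError(f"unknown progeny species {species!r}")


def progeny_amplicon(c: Construct, species: str = INTACT) -> Duplex:
    """Fully base-paired PCR-product duplex for one progeny species."""
    top_seq = LEFT_FLANK + progeny_top_insert(c, species) + RIGHT_FLANK
    top = ChiralStrand.from_str(top_seq, f"{c.name}_progeny_{species}")
    return perfect_duplex(top)


#: Insert read of the strand descending from COM20: CTGCAC at the site region,
#: never cleavable by PstI in either orientation.
COM20_PROGENY_INSERT = "AATTCTCGTGCAGGCTAGCACTGA"


def com20_amplicon() -> Duplex:
    """PCR-product duplex descending from the COM20 (complement) strand."""
    top = ChiralStrand.from_str(
        LEFT_FLANK + COM20_PROGENY_INSERT + RIGHT_FLANK, "COM20_progeny"
    )
    return perfect_duplex(top)


def recombinant_amplicon(c: Construct) -> Duplex:
    """The original ligated hetero-duplex in its amplicon context.

    Top strand: flanks + the construct's (possibly lesion-bearing) insert
    strand.  Bottom strand: perfect complement over the flanks, COM20 over
    the insert region — which places the C:C mismatch inside the PstI site
    and, for most constructs, a second mismatch opposite the lesion.
    """
    L = len(LEFT_FLANK)
    top_seq = LEFT_FLANK + c.insert.top.seq + RIGHT_FLANK
    l_positions = tuple(L + p for p in c.insert.top.l_positions)
    top = ChiralStrand.from_str(top_seq, f"{c.name}_recombinant", l_positions=l_positions)
    # bottom laid out per alignment column (3'→5' left to right), then reversed
    by_col = [complement_base(b) for b in top_seq]
    for col in range(L + 5, L + 29):  # COM20 spans insert pos 5..24 + AGCT junction
        by_col[col - 1] = COM20_SEQ[L + 29 - col - 1]
    bottom = ChiralStrand.from_str("".join(reversed(by_col)), f"{c.name}_rec_bottom")
    return Duplex(top=top, bottom=bottom, top_offset=0, bottom_offset=0)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "name",
    "lesion_base",
    "chirality",
    "lesion_position",
    "detected_incorporation",
    "outcome_label",
)


def export_constructs(
    constructs: list[Construct],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write insert strands (+COM20) as FASTA and a construct annotation TSV."""
    strands = [c.insert.top for c in constructs] + [_com20_strand()]
    # chirality is carried by the annotation table, column 'lesion_position'
    write_strands_fasta(strands, fasta_path, sidecar_path=None)
    with open(annotation_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for c in constructs:
            w.writerow(
                [
                    c.name,
                    c.lesion.base if c.lesion else "",
                    c.lesion.chirality if c.lesion else "",
                    c.lesion_position if c.lesion_position is not None else "",
                    c.detected_incorporation or "",
                    c.outcome_label,
                ]
            )


DECODE_COLUMNS = ("lesion", "construct", "detected_incorporation", "outcome_label")


def write_decode_table(dt: DecodeTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(DECODE_COLUMNS)
        for name, (detected, label) in dt.entries.items():
            w.writerow([dt.lesion, name, detected, label])


def read_decode_table(path: str | Path) -> DecodeTable:
    entries: dict[str, tuple[str, str]] = {}
    lesion = None
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        if r.fieldnames is None or tuple(r.fieldnames) != DECODE_COLUMNS:
            raise InputError(f"decode table {path} must have columns {DECODE_COLUMNS}")
        for row in r:
            lesion = row["lesion"]
            entries[row["construct"]] = (
                row["detected_incorporation"],
                row["outcome_label"],
            )
    if lesion is None or not entries:
        raise InputError(f"decode table {path} is empty")
    return DecodeTable(lesion=lesion, entries=entries)
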