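"""SVMP domain-architecture annotation and class assignment.

Snake venom metalloproteinase (SVMP) precursors fall into three classes by
domain composition: P-I (catalytic domain only), P-II (catalytic +
disintegrin) and P-III (catalytic + disintegrin-like + cysteine-rich).
Disintegrin domains carry the integrin-binding RGD tripeptide, while
disintegrin-like domains carry ECD instead; the catalytic domain carries the
reprolysin zinc-binding consensus H-E-x-x-H-x-x-G-x-x-H whose histidines
coordinate the catalytic zinc. This module annotates translated cDNAs with
these features and assigns each transcript to a class using motif evidence
plus coding length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import seqio

#: Default class-length thresholds (nt). Chosen from the gap structure of
#: observed transcript lengths (P-I roughly 650-830 nt, P-II 920-1070 nt,
#: P-III 1250-1360 nt): sequences shorter than L12 without motifs are P-I,
#: sequences above L23 with ECD are P-III.
DEFAULT_L12 = 900
DEFAULT_L23 = 1200

ZINC_CONSENSUS = "HEXXHXXGXXH"
#: 0-based offsets of the anchor residues within the 11-residue zinc window.
_ZINC_ANCHORS = {0: "H", 1: "E", 4: "H", 7: "G", 10: "H"}
_ZINC_H_OFFSETS = (0, 4, 10)


@dataclass(frozen=True)
class DomainBoundaries:
    """Amino-acid domain spans in the numbering of a reference sequence."""

    catalytic_aa: tuple[int, int] = (1, 214)
    disintegrin_aa: tuple[int, int] = (215, 307)
    reference_id: str | None = None

    def __post_init__(self) -> None:
        c1, c2 = self.catalytic_aa
        d1, d2 = self.disintegrin_aa
        if not (1 <= c1 <= c2 < d1 <= d2):
            raise ValueError(
                f"domain spans must be ordered and non-overlapping, got "
                f"catalytic={self.catalytic_aa}, disintegrin={self.disintegrin_aa}"
            )


@dataclass
class ZincMotifStatus:
    """Best match to the reprolysin zinc-binding consensus in a protein."""

    found: bool
    start: int | None = None  # 1-based position of the 11-residue window
    pattern_residues: str = ""
    h_substitutions: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class DomainArchitecture:
    """Per-sequence class call plus motif and domain evidence."""

    id: str
    svmp_class: str = "unknown"  # P-I | P-II | P-III | unknown
    subclass: str = "none"  # a | b | x | none (filled from phylogenetic evidence)
    coding_length_nt: int = 0
    rgd_positions: list[int] = field(default_factory=list)
    ecd_positions: list[int] = field(default_factory=list)
    zinc_motif: ZincMotifStatus = field(default_factory=lambda: ZincMotifStatus(False))
    nglyc_positions: list[int] = field(default_factory=list)
    cysteine_positions: list[int] = field(default_factory=list)
    extra_cysteines: list[int] = field(default_factory=list)
    missing_cysteines: list[int] = field(default_factory=list)


def find_tripeptide_motifs(aa: str) -> tuple[list[int], list[int]]:
    """All 1-based start positions of the exact substrings RGD and ECD."""
    if not aa:
        raise ValueError("empty protein sequence")
    rgd = [i + 1 for i in range(len(aa) - 2) if aa[i : i + 3] == "RGD"]
    ecd = [i + 1 for i in range(len(aa) - 2) if aa[i : i + 3] == "ECD"]
    return rgd, ecd


def find_nglyc(aa: str) -> list[int]:
    """1-based positions of N-glycosylation sequons N-X-S/T with X != P."""
    return [
        i + 1
        for i in range(len(aa) - 2)
        if aa[i] == "N" and aa[i + 1] != "P" and aa[i + 2] in "ST"
    ]


def find_zinc_motif(aa: str) -> ZincMotifStatus:
    """Locate the best match to the zinc-binding consensus H-E-x-x-H-x-x-G-x-x-H.

    The three histidines and the glutamate may be substituted. An anchor
    counts as matched when the consensus residue is present, or when an H
    anchor carries tyrosine — the known catalysis-abolishing H->Y substitution,
    which must remain detectable (it is reported in ``h_substitutions``, as is
    any other residue at an H anchor of a found motif). A window is accepted
    when at least 3 of the 5 anchors match; ties in match count are broken by
    exact-residue count, then by the leftmost window.
    """
    n = len(aa)
    if n < 11:
        return ZincMotifStatus(found=False)
    best: tuple[int, int, int] | None = None  # (-matched, -exact, start0)
    for start in range(n - 10):
        window = aa[start : start + 11]
        exact = sum(1 for off, res in _ZINC_ANCHORS.items() if window[off] == res)
        tolerated = sum(1 for off in _ZINC_H_OFFSETS if window[off] == "Y")
        matched = exact + tolerated
        key = (-matched, -exact, start)
        if best is None or key < best:
            best = key
    matched = -best[0]
    if matched < 3:
        return ZincMotifStatus(found=False)
    start0 = best[2]
    window = aa[start0 : start0 + 11]
    subs = [
        (start0 + off + 1, window[off]) for off in _ZINC_H_OFFSETS if window[off] != "H"
    ]
    return ZincMotifStatus(
        found=True, start=start0 + 1, pattern_residues=window, h_substitutions=subs
    )


def cysteine_profile(
    aa: str, reference_positions: list[int]
) -> tuple[list[int], list[int], list[int]]:
    """Cysteine positions versus a reference profile (same numbering as ``aa``).

    Returns ``(positions, extra, missing)`` where extra/missing are the set
    differences against the reference positions.
    """
    positions = [i + 1 for i, res in enumerate(aa) if res == "C"]
    ref = set(reference_positions)
    extra = sorted(set(positions) - ref)
    missing = sorted(ref - set(positions))
    return positions, extra, missing


def _orf_translation(seq: str) -> tuple[str, int]:
    """Frame-0 translation up to the first stop; returns (protein, coding_nt).

    ``coding_nt`` includes the stop codon when one is present, otherwise the
    full sequence length (open reading frame running off the 3' end).
    """
    full = seqio.translate(seq, frame=0)
    stop = full.find("*")
    if stop >= 0:
        return full[:stop], 3 * stop + 3
    return full, len(seq)


def assign_class(
    record: seqio.SequenceRecord,
    boundaries: DomainBoundaries | None = None,
    l12: int = DEFAULT_L12,
    l23: int = DEFAULT_L23,
    reference_cysteines: list[int] | None = None,
) -> DomainArchitecture:
    """Assign a mature-protein coding cDNA to class P-I / P-II / P-III.

    Decision rule, in precedence order on the frame-0 translation:
    ECD present and coding length > ``l23`` -> P-III; RGD present and coding
    length <= ``l23`` -> P-II; neither motif and coding length < ``l12`` ->
    P-I; anything else (motif/length conflict) -> unknown, with a warning.
    The P-II subclass (a/b/x) requires phylogenetic evidence and is left
    ``none`` here.
    """
    if record.moltype != "nt":
        raise TypeError("assign_class requires a nucleotide record")
    if len(record.seq) < 3:
        raise ValueError(f"record {record.id!r}: no in-frame translation")
    protein, coding_nt = _orf_translation(record.seq)
    if not protein:
        raise ValueError(f"record {record.id!r}: no in-frame translation")

    rgd, ecd = find_tripeptide_motifs(protein)
    zinc = find_zinc_motif(protein)
    nglyc = find_nglyc(protein)
    cys, extra, missing = cysteine_profile(protein, reference_cysteines or [])

    if ecd and coding_nt > l23:
        svmp_class = "P-III"
    elif rgd and coding_nt <= l23:
        svmp_class = "P-II"
    elif not rgd and not ecd and coding_nt < l12:
        svmp_class = "P-I"
    else:
        svmp_class = "unknown"
        warnings.warn(
            f"record {record.id!r}: motif and length evidence conflict "
            f"(rgd={bool(rgd)}, ecd={bool(ecd)}, coding={coding_nt} nt); "
            "class set to unknown",
            stacklevel=2,
        )

    return DomainArchitecture(
        id=record.id,
        svmp_class=svmp_class,
        subclass="none",
        coding_length_nt=coding_nt,
        rgd_positions=rgd,
        ecd_positions=ecd,
        zinc_motif=zinc,
        nglyc_positions=nglyc,
        cysteine_positions=cys,
        extra_cysteines=extra if reference_cysteines else [],
        missing_cysteines=missing if reference_cysteines else [],
    )


def write_architecture_table(
    architectures: list[DomainArchitecture], path: str
) -> None:
    """Write an architecture report TSV."""
    cols = (
        "id\tclass\tsubclass\tcoding_length\trgd\tecd\tzinc_status\t"
        "n_h_substitutions\tnglyc_positions\textra_cysteines\n"
    )
    with open(path, "w") as handle:
        handle.write(cols)
        for arch in architectures:
            zinc = "found" if arch.zinc_motif.found else "absent"
            handle.write(
                f"{arch.id}\t{arch.svmp_class}\t{arch.subclass}\t"
                f"{arch.coding_length_nt}\t"
                f"{','.join(map(str, arch.rgd_positions)) or '-'}\t"
                f"{','.join(map(str, arch.ecd_positions)) or '-'}\t"
                f"{zinc}\t{len(arch.zinc_motif.h_substitutions)}\t"
                f"{','.join(map(str, arch.nglyc_positions)) or '-'}\t"
                f"{','.join(map(str, arch.extra_cysteines)) or '-'}\n"
            )
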