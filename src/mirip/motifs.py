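"""IUPAC-degenerate motif scanning on RNA sequences.

Scans mature-miRNA (single-stranded) sequences for m6A consensus motifs —
UGAC (reported for pri-miRNAs), ADRA (mature miRNAs) and, as an externally
sourced default, the METTL3/WTAP binding consensus GGACU — and annotates
which adenosines inside each match could carry the methyl mark, plus whether
any of them falls inside the miRNA seed region (positions 2-8).

Coordinates are 1-based and inclusive, on the given strand only; there is no
reverse-complement scanning because a mature miRNA is single-stranded. U and
T are equivalent everywhere. An N in the *sequence* never matches (the
conservative choice), while N in a *pattern* matches any base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import FormatError, ValidationError

#: IUPAC nucleotide codes over the RNA alphabet (T normalized to U).
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

SEQUENCE_ALPHABET = frozenset("ACGUTN")

#: Default seed region of a mature miRNA (1-based, inclusive).
SEED_START, SEED_END = 2, 8


def _normalize(symbol: str) -> str:
    return "U" if symbol.upper() == "T" else symbol.upper()


def iupac_matches(code: str, base: str) -> bool:
    """True iff *base* is in the expansion of IUPAC *code*.

    U and T are interchangeable on both sides. An N base in a sequence
    matches no code (conservative).
    """
    c = _normalize(code)
    if c not in IUPAC_EXPANSION:
        raise FormatError(f"invalid IUPAC symbol {code!r}")
    b = _normalize(base)
    if b == "N":
        return False
    if b not in IUPAC_EXPANSION or len(IUPAC_EXPANSION[b]) != 1:
        raise FormatError(f"invalid nucleotide {base!r}")
    return b in IUPAC_EXPANSION[c]


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC-degenerate motif.

    Must contain at least one symbol whose expansion includes A, otherwise
    no match could ever carry a methylatable adenosine.
    """

    pattern_id: str
    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValidationError(f"pattern {self.pattern_id!r} is empty")
        norm = "".join(_normalize(s) for s in self.symbols)
        for s in norm:
            if s not in IUPAC_EXPANSION:
                raise FormatError(
                    f"pattern {self.pattern_id!r}: invalid IUPAC symbol {s!r}"
                )
        if not any("A" in IUPAC_EXPANSION[s] for s in norm):
            raise ValidationError(
                f"pattern {self.pattern_id!r} can never contain an adenosine"
            )
        object.__setattr__(self, "symbols", norm)

    def __len__(self) -> int:
        return len(self.symbols)


#: Consensus motifs shipped by default. GGACU is the METTL3/WTAP binding
#: consensus from the RNA-methylation literature, not measured here.
DEFAULT_PATTERNS: tuple[MotifPattern, ...] = (
    MotifPattern("UGAC", "UGAC"),      # pri-miRNA m6A consensus
    MotifPattern("ADRA", "ADRA"),      # mature-miRNA m6A consensus
    MotifPattern("METTL3_WTAP", "GGACU"),  # externally sourced writer consensus
)


@dataclass(frozen=True)
class MotifHit:
    """One degenerate-motif match; coordinates 1-based inclusive."""

    pattern_id: str
    start: int
    end: int
    matched: str
    adenosine_offsets: tuple[int, ...]

    def adenosine_positions(self) -> tuple[int, ...]:
        """Absolute 1-based sequence positions of the matched adenosines."""
        return tuple(self.start + off - 1 for off in self.adenosine_offsets)


def _validate_sequence(seq: str) -> str:
    up = seq.upper()
    for i, ch in enumerate(up, start=1):
        if ch not in SEQUENCE_ALPHABET:
            raise FormatError(f"invalid character {ch!r} at position {i}")
    return up


def scan_motifs(
    seq: str, patterns: Iterable[MotifPattern] = DEFAULT_PATTERNS
) -> list[MotifHit]:
    """All overlapping matches of every pattern, at every offset.

    Hits are sorted by (start, pattern_id). Adenosine offsets are 1-based
    within the match and computed on the normalized (U) alphabet.
    """
    raw = _validate_sequence(seq)
    norm = "".join(_normalize(c) for c in raw)
    hits: list[MotifHit] = []
    for pat in patterns:
        plen = len(pat)
        for start0 in range(0, len(norm) - plen + 1):
            window = norm[start0 : start0 + plen]
            if any(w == "N" for w in window):
                continue
            if all(w in IUPAC_EXPANSION[s] for s, w in zip(pat.symbols, window)):
                offsets = tuple(
                    k + 1 for k, w in enumerate(window) if w == "A"
                )
                hits.append(
                    MotifHit(
                        pattern_id=pat.pattern_id,
                        start=start0 + 1,
                        end=start0 + plen,
                        matched=raw[start0 : start0 + plen],
                        adenosine_offsets=offsets,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.pattern_id))
    return hits


def seed_overlap(
    hit: MotifHit, seed_start: int = SEED_START, seed_end: int = SEED_END
) -> bool:
    """True iff any adenosine of the hit lies inside [seed_start, seed_end]."""
    if seed_start > seed_end:
        raise ValidationError("seed_start must be <= seed_end")
    return any(
        seed_start <= pos <= seed_end for pos in hit.adenosine_positions()
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file (RNA or DNA alphabet)."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def packaged_mir200b_fasta() -> Path:
    """Path to the packaged mature hsa-miR-200b-3p sequence (miRBase MIMAT0000318)."""
    return Path(__file__).parent / "data" / "hsa-miR-200b-3p.fa"


def hits_to_bed(
    hits: Sequence[MotifHit], name: str
) -> str:
    """BED-like TSV: name, 0-based half-open start, end, pattern, adenosines."""
    lines = []
    for h in hits:
        adeno = ",".join(str(p) for p in h.adenosine_positions())
        lines.append(f"{name}\t{h.start - 1}\t{h.end}\t{h.pattern_id}\t{adeno}")
    return "\n".join(lines) + ("\n" if lines else "")
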