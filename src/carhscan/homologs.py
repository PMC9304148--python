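"""CarH/CarA homologue classification from degenerate protein motifs.

CarH-family photoreceptor/repressors share a two-domain architecture:
an N-terminal MerR-type winged-helix DNA-binding domain (DBD) whose
recognition helix carries an RxWERRY motif, and a C-terminal
cobalamin-binding domain (CBD) with the classic
D/ExHx2G/Px41SxT/Vx(22-27)GG B12-binding motif.  CarH proteins
additionally conserve a Wx9EH motif (the Trp contacts the adenosyl
group of bound AdoCbl); B12-independent CarA paralogues retain the
B12-binding motif and the E-H pair but have lost the Trp.  Whether an
intact Wx9EH motif co-occurs with the B12-binding motif therefore
separates CarH from CarA homologues, and that co-occurrence rule is the
classifier implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "MotifSpec",
    "MotifHit",
    "DomainSplit",
    "HomologCall",
    "WX9EH",
    "B12_BINDING",
    "RXWERRY",
    "DEFAULT_MOTIFS",
    "LENGTH_RANGE",
    "MIN_REFERENCE_IDENTITY",
    "find_motif",
    "split_domains",
    "classify_homolog",
    "pairwise_identity",
    "identity_matrix",
]

AA = "ACDEFGHIKLMNPQRSTVWY"

# Homologue acceptance filters used alongside the motif criterion.
LENGTH_RANGE = (286, 330)
MIN_REFERENCE_IDENTITY = 29.0  # percent, applied when references are given


@dataclass(frozen=True)
class MotifElement:
    """One element of a degenerate motif: fixed alternatives or a spacer."""

    allowed: frozenset[str] | None  # None -> wildcard spacer
    min_len: int = 1
    max_len: int = 1

    def __post_init__(self) -> None:
        if self.min_len < 0 or self.max_len < self.min_len:
            raise ValueError(f"invalid spacer bounds {self.min_len}..{self.max_len}")


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate amino-acid pattern with bounded-length spacers.

    Elements are matched left to right; a spacer element matches any
    ``min_len``..``max_len`` residues.  ``X`` in the query sequence is
    tolerated but never satisfies a fixed-residue element.
    """

    name: str
    elements: tuple[MotifElement, ...]

    @classmethod
    def parse(cls, name: str, pattern: str) -> "MotifSpec":
        """Build a spec from a compact notation.

        Tokens separated by ``-``: ``W`` fixed residue, ``[DE]``
        alternatives, ``x9`` fixed-length spacer, ``x22:27`` bounded
        spacer.
        """
        elements: list[MotifElement] = []
        for tok in pattern.split("-"):
            if tok.startswith("x"):
                body = tok[1:] or "1"
                if ":" in body:
                    lo, hi = body.split(":")
                    elements.append(MotifElement(None, int(lo), int(hi)))
                else:
                    n = int(body)
                    elements.append(MotifElement(None, n, n))
            elif tok.startswith("["):
                residues = tok.strip("[]")
                elements.append(MotifElement(frozenset(residues)))
            else:
                for ch in tok:
                    elements.append(MotifElement(frozenset(ch)))
        return cls(name=name, elements=tuple(elements))

    @property
    def min_length(self) -> int:
        return sum(e.min_len for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_len for e in self.elements)


# Default motif definitions. Spacer bounds are exactly the published
# x41 and x22-27 of the B12-binding motif; all are configurable by
# constructing alternative MotifSpec objects.
WX9EH = MotifSpec.parse("Wx9EH", "W-x9-EH")
B12_BINDING = MotifSpec.parse("B12_binding", "[DE]-x-H-x2-[GP]-x41-S-x-[TV]-x22:27-GG")
RXWERRY = MotifSpec.parse("RxWERRY", "R-x-WERRY")
DEFAULT_MOTIFS = (WX9EH, B12_BINDING, RXWERRY)

DEFAULT_WING_ALLOWANCE = 30  # residues appended to RxWERRY for the DBD wing


@dataclass(frozen=True)
class MotifHit:
    """A located motif match; positions are 1-based inclusive."""

    motif: str
    start: int
    end: int
    matched_span: str


@dataclass(frozen=True)
class DomainSplit:
    """DBD/CBD boundary: dbd_end is the last DBD residue."""

    dbd_end: int
    cbd_start: int


@dataclass(frozen=True)
class HomologCall:
    """Classification of one protein with its motif evidence."""

    label: str  # CarH | CarA | ambiguous | non_member
    evidence: dict
    passed_filters: bool
    length: int


def find_motif(seq: str, spec: MotifSpec) -> list[MotifHit]:
    """All matches of a degenerate motif, in position order.

    Every admissible spacer length is explored, so several hits may
    share a start position; overlapping hits are allowed.  Identical
    (start, end) duplicates are collapsed.  An empty sequence yields an
    empty list.
    """
    s = seq.upper()
    hits: list[MotifHit] = []
    n = len(s)
    seen: set[tuple[int, int]] = set()

    def extend(pos: int, elem_idx: int, start: int) -> None:
        if elem_idx == len(spec.elements):
            key = (start, pos)
            if key not in seen:
                seen.add(key)
                hits.append(
                    MotifHit(spec.name, start + 1, pos, s[start:pos])
                )
            return
        elem = spec.elements[elem_idx]
        if elem.allowed is None:
            for k in range(elem.min_len, elem.max_len + 1):
                if pos + k > n:
                    break
                extend(pos + k, elem_idx + 1, start)
        else:
            if pos < n and s[pos] in elem.allowed:
                extend(pos + 1, elem_idx + 1, start)

    for start in range(0, n - spec.min_length + 1):
        extend(start, 0, start)
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def split_domains(
    seq: str,
    hits: Sequence[MotifHit],
    wing_allowance: int = DEFAULT_WING_ALLOWANCE,
) -> DomainSplit:
    """Place the DBD/CBD boundary downstream of the recognition helix.

    The boundary is a declared heuristic: the end of the (first)
    RxWERRY hit plus a wing allowance (default 30 residues, covering
    the winged-helix wing), capped so the CBD is non-empty.
    """
    rx = [h for h in hits if h.motif == "RxWERRY"]
    if not rx:
        raise ValueError("cannot split domains: no RxWERRY hit")
    dbd_end = min(rx[0].end + wing_allowance, len(seq) - 1)
    return DomainSplit(dbd_end=dbd_end, cbd_start=dbd_end + 1)


def classify_homolog(
    seq: str,
    motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS,
    length_range: tuple[int, int] = LENGTH_RANGE,
) -> HomologCall:
    """Classify a protein as CarH, CarA, ambiguous or non_member.

    Rules (motif co-occurrence criterion):

    * no B12-binding motif            -> non_member
    * B12 + Wx9EH                     -> CarH
    * B12 + RxWERRY, no Wx9EH         -> CarA
    * B12 only                        -> ambiguous

    A length outside the homologue acceptance range (286-330 aa by
    default) flags ``passed_filters=False`` but the label is still
    reported.
    """
    s = seq.upper()
    by_name = {m.name: find_motif(s, m) for m in motifs}
    has = {name: bool(h) for name, h in by_name.items()}
    if not has.get("B12_binding", False):
        label = "non_member"
    elif has.get("Wx9EH", False):
        label = "CarH"
    elif has.get("RxWERRY", False):
        label = "CarA"
    else:
        label = "ambiguous"
    lo, hi = length_range
    return HomologCall(
        label=label,
        evidence={
            "hits": by_name,
            "has_Wx9EH": has.get("Wx9EH", False),
            "has_B12_binding": has.get("B12_binding", False),
            "has_RxWERRY": has.get("RxWERRY", False),
        },
        passed_filters=lo <= len(s) <= hi,
        length=len(s),
    )


def _make_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # terminal gaps are free so that identity over the aligned core is
    # meaningful for proteins of unequal length
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity from a global affine-gap BLOSUM62 alignment.

    Identity = identical columns / aligned columns, where aligned
    columns span from the first to the last column in which both
    sequences carry a residue (terminal gaps excluded; internal gap
    columns count in the denominator).  Symmetric and in [0, 100].
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 100.0
    aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    core = [i for i in range(len(sa)) if sa[i] != "-" and sb[i] != "-"]
    if not core:
        return 0.0
    lo, hi = core[0], core[-1]
    identical = sum(1 for i in range(lo, hi + 1) if sa[i] == sb[i] and sa[i] != "-")
    return 100.0 * identical / (hi - lo + 1)


def identity_matrix(
    records: Sequence,
    references: Sequence,
    splits: dict | None = None,
    ref_splits: dict | None = None,
):
    """Percent-identity table of records x references.

    Whole-protein identities always; DBD-only and CBD-only identities
    where a DomainSplit is available for both members of the pair
    (missing splits leave those cells NaN).  Returns a pandas DataFrame
    with a MultiIndex column per (reference, region).
    """
    import numpy as np
    import pandas as pd

    splits = splits or {}
    ref_splits = ref_splits or {}
    regions = ("full", "DBD", "CBD")
    cols = pd.MultiIndex.from_product(
        [[r.id for r in references], regions], names=["reference", "region"]
    )
    data = np.full((len(records), len(cols)), np.nan)
    for i, rec in enumerate(records):
        for j, ref in enumerate(references):
            data[i, 3 * j] = pairwise_identity(rec.sequence, ref.sequence)
            sp, rp = splits.get(rec.id), ref_splits.get(ref.id)
            if sp is not None and rp is not None:
                data[i, 3 * j + 1] = pairwise_identity(
                    rec.sequence[: sp.dbd_end], ref.sequence[: rp.dbd_end]
                )
                data[i, 3 * j + 2] = pairwise_identity(
                    rec.sequence[sp.cbd_start - 1 :], ref.sequence[rp.cbd_start - 1 :]
                )
    return pd.DataFrame(data, index=[r.id for r in records], columns=cols)
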