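"""Tandem 11-bp direct-repeat operator discovery in promoter windows.

CarH/CarA operators are runs of abutting 11-bp direct repeats.  A fully
conserved repeat (DR) reads T at position 5 and ACA at positions 8-10
(the TnnACA core); a pseudo-repeat (dr) sits in the same tandem register
but does not fully conserve the core.  The scanner finds every maximal
run of contiguous 11-mers matching a permissive ("loose") pattern,
requires the run to contain at least one stringent ("strict") match,
and then labels each unit DR or dr.

Three nested default patterns are used (positions 1-based within the
11-mer):

* ``loose``  — T at 5, C at 9; everything else free.
* ``strict`` — T at 5, R (A/G) at 8, C at 9, R at 10.
* ``DR_label`` — T at 5 and exactly A, C, A at 8, 9, 10.

so DR_label ⊂ strict ⊂ loose.  A "methods-literal" preset reading the
bracketed bases of the published search pattern as fixed is also
shipped; both are configurable position-by-position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io import PromoterWindow

__all__ = [
    "RepeatPattern",
    "RepeatUnit",
    "OperatorCall",
    "PFM",
    "ScanParams",
    "LOOSE",
    "STRICT",
    "DR_LABEL",
    "METHODS_LITERAL_LOOSE",
    "METHODS_LITERAL_STRICT",
    "REPEAT_LENGTH",
    "match_pattern",
    "label_repeat",
    "scan_tandem_repeats",
    "arrangement_string",
    "build_pfm",
    "scan_genome",
]

REPEAT_LENGTH = 11

_PURINE = frozenset("AG")
_ANY = frozenset("ACGT")


@dataclass(frozen=True)
class RepeatPattern:
    """Per-position allowed-base constraints over an 11-mer.

    ``constraints`` maps 1-based positions to allowed base sets; any
    position absent from the mapping is unconstrained.  ``N`` in the
    scanned sequence never satisfies a constrained position.
    """

    name: str
    constraints: Mapping[int, frozenset[str]]

    def __post_init__(self) -> None:
        for pos, allowed in self.constraints.items():
            if not 1 <= pos <= REPEAT_LENGTH:
                raise ValueError(f"pattern {self.name!r}: position {pos} out of 1..11")
            if not allowed or not set(allowed) <= set("ACGT"):
                raise ValueError(
                    f"pattern {self.name!r}: invalid base set {sorted(allowed)} at {pos}"
                )


LOOSE = RepeatPattern("loose", {5: frozenset("T"), 9: frozenset("C")})
STRICT = RepeatPattern(
    "strict",
    {5: frozenset("T"), 8: _PURINE, 9: frozenset("C"), 10: _PURINE},
)
DR_LABEL = RepeatPattern(
    "DR_label",
    {5: frozenset("T"), 8: frozenset("A"), 9: frozenset("C"), 10: frozenset("A")},
)

# Literal reading of the published search grammar, with the bracketed
# trailing bases treated as fixed: N4-T-N3-C[C][G] and N4-T-N2-RCR[G].
METHODS_LITERAL_LOOSE = RepeatPattern(
    "methods_literal_loose",
    {5: frozenset("T"), 9: frozenset("C"), 10: frozenset("C"), 11: frozenset("G")},
)
METHODS_LITERAL_STRICT = RepeatPattern(
    "methods_literal_strict",
    {5: frozenset("T"), 8: _PURINE, 9: frozenset("C"), 10: _PURINE, 11: frozenset("G")},
)

# Positions of the TnnACA core within the 11-mer (1-based).
_CORE_POSITIONS = (5, 8, 9, 10)


@dataclass(frozen=True)
class RepeatUnit:
    """One 11-bp repeat within an operator call."""

    index: int  # 1-based order within the operator, 5'->3'
    offset: int  # 0-based start within the window sequence
    elevenmer: str
    label: str  # "DR" or "dr"
    strict_match: bool
    mismatches: tuple[int, ...]  # TnnACA core positions not conserved


@dataclass(frozen=True)
class OperatorCall:
    """A maximal run of contiguous tandem 11-bp repeats."""

    gene_id: str
    window_offset: int  # 0-based start of the run within the window
    repeats: tuple[RepeatUnit, ...]
    n_strict: int
    n_DR: int

    @property
    def span_bp(self) -> int:
        return REPEAT_LENGTH * len(self.repeats)

    @property
    def arrangement(self) -> str:
        return arrangement_string(self)

    @property
    def sequence(self) -> str:
        return "".join(u.elevenmer for u in self.repeats)


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix over the 11 repeat positions."""

    counts: tuple[tuple[int, int, int, int], ...]  # 11 columns x (A,C,G,T)
    n_sequences: int

    BASES = "ACGT"

    def consensus(self) -> str:
        out = []
        for col in self.counts:
            best = max(col)
            winners = [b for b, c in zip(self.BASES, col) if c == best]
            out.append(winners[0] if len(winners) == 1 else _ambiguity(winners))
        return "".join(out)

    def to_rows(self) -> list[dict]:
        return [
            {"position": i + 1, **dict(zip(self.BASES, col))}
            for i, col in enumerate(self.counts)
        ]


_IUPAC = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


def _ambiguity(bases: Sequence[str]) -> str:
    return _IUPAC[frozenset(bases)]


@dataclass(frozen=True)
class ScanParams:
    """Tunable scanner parameters (defaults match the package presets)."""

    loose: RepeatPattern = LOOSE
    strict: RepeatPattern = STRICT
    dr_label: RepeatPattern = DR_LABEL
    min_repeats: int = 3
    min_strict: int = 1

    @classmethod
    def methods_literal(cls, **kw) -> "ScanParams":
        return cls(loose=METHODS_LITERAL_LOOSE, strict=METHODS_LITERAL_STRICT, **kw)


def match_pattern(elevenmer: str, pattern: RepeatPattern) -> bool:
    """True iff every constrained position holds an allowed base.

    Input must be exactly 11 bases over ACGTN; ``N`` never matches a
    constrained position.
    """
    if len(elevenmer) != REPEAT_LENGTH:
        raise ValueError(
            f"expected an 11-mer, got {len(elevenmer)} bases: {elevenmer!r}"
        )
    s = elevenmer.upper()
    if not set(s) <= set("ACGTN"):
        raise ValueError(f"invalid bases in {elevenmer!r}")
    return all(s[pos - 1] in allowed for pos, allowed in pattern.constraints.items())


def label_repeat(index: int, offset: int, elevenmer: str, params: ScanParams) -> RepeatUnit:
    s = elevenmer.upper()
    is_dr = match_pattern(s, params.dr_label)
    mismatches = tuple(
        p for p in _CORE_POSITIONS
        if s[p - 1] not in params.dr_label.constraints[p]
    )
    return RepeatUnit(
        index=index,
        offset=offset,
        elevenmer=s,
        label="DR" if is_dr else "dr",
        strict_match=match_pattern(s, params.strict),
        mismatches=mismatches,
    )


def _candidate_runs(seq: str, params: ScanParams) -> list[tuple[int, int]]:
    """All maximal (offset, n_repeats) runs of contiguous loose 11-mers."""
    n = len(seq)
    loose_at = [
        match_pattern(seq[i : i + REPEAT_LENGTH], params.loose)
        for i in range(max(n - REPEAT_LENGTH + 1, 0))
    ]
    runs = []
    for i, ok in enumerate(loose_at):
        if not ok:
            continue
        if i >= REPEAT_LENGTH and loose_at[i - REPEAT_LENGTH]:
            continue  # not maximal: extends a run starting upstream
        k = 1
        while i + k * REPEAT_LENGTH < len(loose_at) and loose_at[i + k * REPEAT_LENGTH]:
            k += 1
        runs.append((i, k))
    return runs


def scan_tandem_repeats(
    window: PromoterWindow | str,
    params: ScanParams | None = None,
    gene_id: str | None = None,
) -> list[OperatorCall]:
    """Find candidate operators in a promoter window.

    Reports every maximal run of contiguous (step 11) loose-matching
    11-mers of length >= ``min_repeats`` containing >= ``min_strict``
    strict matches.  Runs overlapping in different registers are
    resolved deterministically: more strict matches wins, then more DR
    labels, then the leftmost.  Calls are returned sorted by offset.
    """
    params = params or ScanParams()
    if isinstance(window, PromoterWindow):
        seq, gid = window.sequence.upper(), window.gene_id
    else:
        seq, gid = str(window).upper(), gene_id or ""

    calls: list[OperatorCall] = []
    for offset, k in _candidate_runs(seq, params):
        if k < params.min_repeats:
            continue
        units = tuple(
            label_repeat(j + 1, offset + j * REPEAT_LENGTH,
                         seq[offset + j * REPEAT_LENGTH : offset + (j + 1) * REPEAT_LENGTH],
                         params)
            for j in range(k)
        )
        n_strict = sum(u.strict_match for u in units)
        if n_strict < params.min_strict:
            continue
        calls.append(OperatorCall(
            gene_id=gid,
            window_offset=offset,
            repeats=units,
            n_strict=n_strict,
            n_DR=sum(u.label == "DR" for u in units),
        ))

    # resolve overlaps between runs in different registers
    calls.sort(key=lambda c: (-c.n_strict, -c.n_DR, c.window_offset))
    kept: list[OperatorCall] = []
    for c in calls:
        c_end = c.window_offset + c.span_bp
        if all(
            c_end <= k.window_offset or k.window_offset + k.span_bp <= c.window_offset
            for k in kept
        ):
            kept.append(c)
    kept.sort(key=lambda c: c.window_offset)
    return kept


def arrangement_string(call: OperatorCall) -> str:
    """Hyphen-joined per-repeat labels with 1-based 5'->3' indices.

    e.g. ``DR1-dr2-DR3-DR4-dr5``.
    """
    if not call.repeats:
        raise ValueError("operator call has no repeats")
    return "-".join(f"{u.label}{u.index}" for u in call.repeats)


def build_pfm(repeats: Iterable[str]) -> tuple[PFM, str]:
    """Count bases per column over aligned 11-mers; return (PFM, consensus).

    Consensus takes the most frequent base per column; ties are reported
    as IUPAC ambiguity codes.
    """
    seqs = [r.upper() for r in repeats]
    if not seqs:
        raise ValueError("cannot build a PFM from zero repeats")
    for s in seqs:
        if len(s) != REPEAT_LENGTH:
            raise ValueError(f"repeat {s!r} is not 11 bases")
    cols = []
    for i in range(REPEAT_LENGTH):
        col = [0, 0, 0, 0]
        for s in seqs:
            if s[i] in PFM.BASES:
                col[PFM.BASES.index(s[i])] += 1
        cols.append(tuple(col))
    pfm = PFM(counts=tuple(cols), n_sequences=len(seqs))
    return pfm, pfm.consensus()


def scan_genome(
    genome_entries,
    features,
    params: ScanParams | None = None,
    upstream: int = 150,
    downstream: int = 25,
):
    """Scan every annotated gene's promoter window; return a report table.

    Returns a pandas DataFrame with one row per (gene, operator call),
    or a single row with an empty arrangement for genes without calls.
    Features whose contig is missing from the FASTA produce an error
    row instead of aborting the scan.  Duplicate gene ids are
    suffix-disambiguated.
    """
    import pandas as pd

    from .io import extract_promoter_window

    params = params or ScanParams()
    contigs = {e.id: e for e in genome_entries}
    seen: dict[str, int] = {}
    rows = []
    for feat in features:
        gid = feat.gene_id
        seen[gid] = seen.get(gid, 0) + 1
        if seen[gid] > 1:
            gid = f"{gid}.{seen[feat.gene_id]}"
        if feat.contig_id not in contigs:
            rows.append({
                "gene_id": gid, "contig_id": feat.contig_id, "status": "error",
                "error": f"contig {feat.contig_id!r} not in FASTA",
            })
            continue
        window = extract_promoter_window(
            contigs[feat.contig_id], feat, upstream=upstream, downstream=downstream
        )
        calls = scan_tandem_repeats(window, params)
        if not calls:
            rows.append({
                "gene_id": gid, "contig_id": feat.contig_id, "status": "no_operator",
                "truncated": window.truncated,
            })
        for call in calls:
            rows.append({
                "gene_id": gid,
                "contig_id": feat.contig_id,
                "status": "operator",
                "window_offset": call.window_offset,
                "gene_frame_start": window.gene_frame_position(call.window_offset),
                "n_repeats": len(call.repeats),
                "span_bp": call.span_bp,
                "arrangement": call.arrangement,
                "n_DR": call.n_DR,
                "n_strict": call.n_strict,
                "sequence": call.sequence,
                "truncated": window.truncated,
            })
    return pd.DataFrame(rows)
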