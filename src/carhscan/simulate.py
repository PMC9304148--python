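"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of (parameters, seed) and record
their ground truth, so every pipeline stage can be exercised without
external data.  Defaults emulate the study system: GC-rich (~68%)
myxobacterial promoter regions, 286-330 aa CarH/CarA-family proteins,
Hill-shaped EMSA titrations at the published probe concentrations, and
Gaussian size-exclusion elution traces placed by the column
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binding import (
    BindingCurve,
    SECCalibration,
    hill,
    sec_elution_volume,
)
from .io import GeneFeature, PromoterWindow, SeqEntry, reverse_complement
from .operators import (
    DR_LABEL,
    REPEAT_LENGTH,
    OperatorCall,
    ScanParams,
    label_repeat,
    match_pattern,
    scan_tandem_repeats,
)

__all__ = [
    "DEFAULT_GC",
    "EMSA_CONCENTRATIONS_NM",
    "PROTEIN_LENGTH_RANGE",
    "gen_promoter",
    "gen_protein",
    "gen_emsa_curve",
    "gen_sec_trace",
    "gen_mini_genome",
]

DEFAULT_GC = 0.68  # midpoint of the 66-75% genomic GC range of the clade
PROTEIN_LENGTH_RANGE = (286, 330)
# EMSA titration series used for the natural promoter probes (nM)
EMSA_CONCENTRATIONS_NM = (0.1, 0.25, 0.5, 1.0, 5.0, 10.0, 100.0)

_BASES = "ACGT"


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_BASES), size=n, p=p))


def _gen_repeat(rng: np.random.Generator, label: str, gc: float,
                n_dr_mismatches: int = 1) -> str:
    """One 11-mer for a planted arrangement slot.

    DR conserves the TnnACA core exactly (T5, A8, C9, A10).  dr keeps
    the loose pattern (T5, C9) but carries ``n_dr_mismatches``
    substitutions within the core at positions 8/10.  ``mutated``
    breaks the loose pattern itself (no T at position 5) so it can
    never be read as a repeat.
    """
    bases = list(_random_bases(rng, REPEAT_LENGTH, gc))
    if label in ("DR", "dr"):
        bases[4], bases[7], bases[8], bases[9] = "T", "A", "C", "A"
        if label == "dr":
            if not 1 <= n_dr_mismatches <= 2:
                raise ValueError("dr units support 1-2 core mismatches (positions 8/10)")
            positions = list(rng.permutation([7, 9]))[:n_dr_mismatches]
            for p in positions:
                bases[p] = str(rng.choice([b for b in "CGT" if b != bases[p]]))
    elif label == "mutated":
        bases[4] = str(rng.choice(list("ACG")))  # kill T5 -> not even loose
        bases[8] = str(rng.choice(list("AGT")))  # and C9 for good measure
    else:
        raise ValueError(f"unknown repeat label {label!r}")
    return "".join(bases)


def _background_is_clean(seq: str, params: ScanParams) -> bool:
    return not scan_tandem_repeats(seq, params)


def gen_promoter(
    arrangement_spec,
    gc: float = DEFAULT_GC,
    seed: int = 0,
    window_length: int = 175,
    params: ScanParams | None = None,
    gene_id: str = "synthetic_gene",
    max_attempts: int = 200,
) -> tuple[PromoterWindow, OperatorCall | None]:
    """A promoter window with a planted tandem-repeat run, plus its truth.

    ``arrangement_spec`` is an ordered list of labels from
    {"DR", "dr", "mutated"}.  The planted run is placed at a seeded
    offset; the background is rejection-sampled until the scanner
    reports exactly the planted operator (or nothing, when the planted
    run is shorter than ``min_repeats`` or interrupted), so tests can
    rely on ground-truth closure.  Returns (window, expected call or
    None).
    """
    if not arrangement_spec:
        raise ValueError("arrangement_spec must contain at least one label")
    params = params or ScanParams()
    rng = _rng(seed)
    run_len = len(arrangement_spec) * REPEAT_LENGTH
    if run_len > window_length:
        raise ValueError("planted run longer than the window")

    for _ in range(max_attempts):
        offset = int(rng.integers(0, window_length - run_len + 1))
        planted = "".join(
            _gen_repeat(rng, label, gc) for label in arrangement_spec
        )
        background = _random_bases(rng, window_length, gc)
        seq = background[:offset] + planted + background[offset + run_len :]

        calls = scan_tandem_repeats(seq, params, gene_id=gene_id)
        expected = _expected_call(seq, offset, arrangement_spec, params, gene_id)
        ok = (
            calls == [expected] if expected is not None else not calls
        )
        if not ok:
            continue
        window = PromoterWindow(
            gene_id=gene_id,
            contig_id="synthetic",
            window_start=1,
            window_end=window_length,
            strand="+",
            sequence=seq,
            offset_of_plus1=150 if window_length == 175 else window_length - 25,
            truncated=False,
        )
        return window, expected
    raise RuntimeError(
        "could not generate a clean background within the rejection budget; "
        "try a different seed"
    )


def _expected_call(seq, offset, arrangement_spec, params, gene_id):
    """Ground-truth OperatorCall for the planted run (None if sub-threshold)."""
    labels = list(arrangement_spec)
    # a 'mutated' unit interrupts the run; the longest clean stretch must
    # itself satisfy min_repeats to be called
    best: tuple[int, int] | None = None
    i = 0
    while i < len(labels):
        if labels[i] == "mutated":
            i += 1
            continue
        j = i
        while j < len(labels) and labels[j] != "mutated":
            j += 1
        if best is None or j - i > best[1] - best[0]:
            best = (i, j)
        i = j
    if best is None:
        return None
    lo, hi = best
    if hi - lo < params.min_repeats:
        return None
    run_offset = offset + lo * REPEAT_LENGTH
    units = tuple(
        label_repeat(
            k + 1,
            run_offset + k * REPEAT_LENGTH,
            seq[run_offset + k * REPEAT_LENGTH : run_offset + (k + 1) * REPEAT_LENGTH],
            params,
        )
        for k in range(hi - lo)
    )
    n_strict = sum(u.strict_match for u in units)
    if n_strict < params.min_strict:
        return None
    return OperatorCall(
        gene_id=gene_id,
        window_offset=run_offset,
        repeats=units,
        n_strict=n_strict,
        n_DR=sum(u.label == "DR" for u in units),
    )


# ---------------------------------------------------------------------------
# proteins

_DBD_SCAFFOLD_LEN = 35  # residues before the recognition helix


def gen_protein(
    kind: str,
    seed: int = 0,
    length: int | None = None,
) -> tuple[SeqEntry, str]:
    """A synthetic CarH-family protein with planted motifs, plus its label.

    * ``CarH``: RxWERRY in the DBD, then Wx9EH and the
      D/ExHx2G/Px41SxT/Vx(22-27)GG B12-binding motif in the CBD.
    * ``CarA``: same layout but the Trp of Wx9EH substituted (the E-H
      pair remains), so only RxWERRY and the B12 motif are intact.
    * ``non_member``: no B12-binding motif (and no Wx9EH).

    Lengths are drawn uniformly from the homologue acceptance range
    286-330 aa; spacer lengths inside the B12 motif are randomised
    within their bounds.  Background residues are drawn from the
    20-letter alphabet with W, E and H excluded outside the planted
    motifs so spurious matches cannot arise.
    """
    if kind not in ("CarH", "CarA", "non_member"):
        raise ValueError(f"unknown protein kind {kind!r}")
    rng = _rng(seed)
    lo, hi = PROTEIN_LENGTH_RANGE
    n = int(length if length is not None else rng.integers(lo, hi + 1))

    # background alphabet avoids W/E/H (and D, G, P, S, T, V are fine:
    # only full-motif matches matter and those need the anchors)
    bg = "ACFIKLMNQRY"

    def draw(k: int) -> str:
        return "".join(rng.choice(list(bg), size=k))

    rxwerry = "R" + draw(1) + "WERRY"
    trp = "W" if kind == "CarH" else draw(1)
    wx9eh = trp + draw(9) + "EH" if kind != "non_member" else draw(12)

    b12_spacer2 = int(rng.integers(22, 28))
    b12 = (
        str(rng.choice(["D", "E"]))
        + draw(1)
        + "H"
        + draw(2)
        + str(rng.choice(["G", "P"]))
        + draw(41)
        + "S"
        + draw(1)
        + str(rng.choice(["T", "V"]))
        + draw(b12_spacer2)
        + "GG"
    )
    if kind == "non_member":
        b12 = draw(len(b12) - 10)  # unstructured filler of similar bulk

    parts = [draw(_DBD_SCAFFOLD_LEN), rxwerry]
    core = "".join(parts)
    # pad between DBD and CBD motifs, then to the target length
    inter = max(n - len(core) - len(wx9eh) - len(b12) - 5, 4)
    seq = core + draw(inter // 2) + wx9eh + draw(inter - inter // 2) + b12
    if len(seq) < n:
        seq += draw(n - len(seq))
    entry = SeqEntry(id=f"synthetic_{kind}_{seed}", sequence=seq,
                     description=f"synthetic {kind} protein")
    return entry, kind


# ---------------------------------------------------------------------------
# EMSA curves and SEC traces


def gen_emsa_curve(
    amplitude: float = 1.0,
    kd_nm: float = 35.0,
    hill_h: float = 2.0,
    concentrations=EMSA_CONCENTRATIONS_NM,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> BindingCurve:
    """A Hill-model fraction-bound titration with optional Gaussian noise.

    Noise is additive, then clipped to [0, 1].  Defaults are the
    CarH_Cfu ground-truth fixture parameters (apparent KD 35 nM,
    cooperative binding h = 2, full amplitude) at the natural-probe
    titration series.
    """
    rng = _rng(seed)
    c = np.asarray(concentrations, dtype=float)
    f = hill(c, amplitude, kd_nm, hill_h)
    if noise_sigma > 0:
        f = f + rng.normal(0.0, noise_sigma, size=f.shape)
    f = np.clip(f, 0.0, 1.0)
    return BindingCurve(tuple(float(x) for x in c), tuple(float(x) for x in f))


def gen_sec_trace(
    oligomers=(2,),
    protomer_mr_kda: float = 35.0,
    calib: SECCalibration | None = None,
    peak_sigma_ml: float = 0.15,
    n_points: int = 600,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """A synthetic SEC elution trace with Gaussian peaks per oligomer.

    Peaks are centred at the elution volume the calibration assigns to
    n x protomer mass.  Returns (ve_grid_ml, absorbance, true_peak_ve).
    """
    calib = calib or SECCalibration()
    if not set(oligomers) <= {1, 2, 3, 4}:
        raise ValueError("oligomeric states must be within 1-4")
    rng = _rng(seed)
    lo, hi = calib.ve_range
    ve = np.linspace(lo, hi, n_points)
    trace = np.zeros_like(ve)
    centers = []
    for n in oligomers:
        center = sec_elution_volume(n * protomer_mr_kda, calib)
        centers.append(center)
        trace += np.exp(-0.5 * ((ve - center) / peak_sigma_ml) ** 2)
    if noise_sigma > 0:
        trace = trace + rng.normal(0.0, noise_sigma, size=trace.shape)
    return ve, trace, tuple(centers)


def pick_sec_peaks(ve: np.ndarray, trace: np.ndarray, min_height: float = 0.2):
    """Elution volumes of trace peaks (scipy peak picking)."""
    from scipy.signal import find_peaks

    idx, _ = find_peaks(trace, height=min_height)
    return tuple(float(ve[i]) for i in idx)


# ---------------------------------------------------------------------------
# mini genomes


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    feature: GeneFeature
    arrangement: tuple[str, ...] | None
    expected_arrangement: str | None


def gen_mini_genome(
    n_genes: int = 5,
    planted: dict | None = None,
    gc: float = DEFAULT_GC,
    seed: int = 0,
    gene_length: int = 300,
    spacing: int = 220,
    params: ScanParams | None = None,
):
    """A single-contig genome with genes on both strands and planted operators.

    ``planted`` maps gene ids (``gene1``..``geneN``) to arrangement
    specs (lists over {DR, dr, mutated}).  Each gene's -150..+25
    promoter window is generated with :func:`gen_promoter` (planted or
    operator-free) and written into the contig in the gene's
    orientation; gene bodies and spacers are random GC-matched filler.
    Returns (SeqEntry, [GeneFeature], truth) where truth maps gene id
    to the expected arrangement string (or None).
    """
    params = params or ScanParams()
    planted = dict(planted or {})
    rng = _rng(seed)
    gene_ids = [f"gene{i + 1}" for i in range(n_genes)]
    unknown = set(planted) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted gene ids not generated: {sorted(unknown)}")

    window_len = 175
    unit = window_len + gene_length + spacing
    contig_parts: list[str] = []
    features: list[GeneFeature] = []
    truth: dict[str, str | None] = {}
    pos = 1  # 1-based genomic cursor
    contig_parts.append(_random_bases(rng, spacing, gc))
    pos += spacing
    for i, gid in enumerate(gene_ids):
        strand = "+" if i % 2 == 0 else "-"
        spec = planted.get(gid)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if spec:
            window, call = gen_promoter(
                spec, gc=gc, seed=sub_seed, params=params, gene_id=gid
            )
            truth[gid] = call.arrangement if call else None
        else:
            window, _ = gen_promoter(
                ["mutated"], gc=gc, seed=sub_seed, params=params, gene_id=gid
            )
            truth[gid] = None
        body = _random_bases(rng, gene_length, gc)
        if strand == "+":
            # window covers [-150, +25]; +1..+25 are the first gene bases
            upstream = window.sequence[:150]
            gene_seq = window.sequence[150:] + body
            contig_parts.append(upstream + gene_seq)
            start = pos + 150
            end = start + len(gene_seq) - 1
        else:
            upstream = window.sequence[:150]
            gene_seq = window.sequence[150:] + body
            genomic = reverse_complement(upstream + gene_seq)
            contig_parts.append(genomic)
            end = pos + len(genomic) - 1 - 150
            start = end - len(gene_seq) + 1
        features.append(GeneFeature(
            contig_id="synthetic_contig", start=start, end=end,
            strand=strand, gene_id=gid,
        ))
        pos += len(contig_parts[-1])
        contig_parts.append(_random_bases(rng, spacing, gc))
        pos += spacing
    contig = SeqEntry(
        id="synthetic_contig",
        sequence="".join(contig_parts),
        description="synthetic mini genome",
    )
    return contig, features, truth


def write_gff3(features, path: str | Path, contig_lengths: dict | None = None) -> None:
    """Write gene features as standard 9-column GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for cid, n in contig_lengths.items():
                fh.write(f"##sequence-region {cid} 1 {n}\n")
        for f in features:
            fh.write(
                f"{f.contig_id}\tcarhscan\tgene\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.gene_id}\n"
            )
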