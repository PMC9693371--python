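"""MYB repeat detection with a position-specific scoring matrix.

The repeat model is a PSSM over the 20-letter alphabet built from a packaged
alignment of MYB-type helix-turn-helix repeats. Windows of the PSSM width are
scored as summed per-column log-odds (bits); the retention threshold is
calibrated on shuffled decoy sequences so that decoy windows pass at a rate
of at most 1e-4, and an E-value per hit comes from a Gumbel fit to the decoy
window-score distribution. Proteins are then classified into the
1R/R2R3/3R/4R subfamilies by the number of full repeats they carry and named
in chromosome order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats

from .io_formats import GenomeAnnotation, SequenceRecord, read_fasta

__all__ = [
    "AA_ALPHABET",
    "RepeatPSSM",
    "MybRepeatHit",
    "MybClassification",
    "ScanConfig",
    "build_pssm",
    "calibrate_pssm",
    "load_packaged_pssm",
    "packaged_repeat_alignment",
    "scan_repeats",
    "classify_subfamily",
    "classify_proteome",
    "assign_names",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass
class RepeatPSSM:
    """Log-odds matrix (bits) for one ~52-residue MYB repeat.

    ``log_odds`` is 20 x width, rows in ``AA_ALPHABET`` order. ``gumbel``
    holds the (loc, scale) of the decoy window-score distribution used for
    E-values; ``n_calibration_windows`` records the decoy search space.
    """

    width: int
    log_odds: np.ndarray
    background: np.ndarray
    bit_threshold: float
    probs: np.ndarray | None = None
    gumbel: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.shape != (20, self.width):
            raise ValueError("log_odds must be 20 x width")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        if self.width < 10:
            raise ValueError("repeat model width must be >= 10")

    def window_evalue(self, bits: float, n_windows: int) -> float:
        loc, scale = self.gumbel
        p = stats.gumbel_r.sf(bits, loc=loc, scale=scale)
        return float(n_windows * p)


@dataclass(frozen=True)
class MybRepeatHit:
    """One retained repeat window (1-based inclusive residue coordinates)."""

    protein_id: str
    start: int
    end: int
    bits: float
    evalue: float
    matched_columns: int = 0


@dataclass
class MybClassification:
    protein_id: str
    n_repeats: int
    n_partial: int
    subfamily: str
    assigned_name: str = ""
    hits: list[MybRepeatHit] = field(default_factory=list)


@dataclass(frozen=True)
class ScanConfig:
    """Family-identification thresholds.

    ``evalue_max`` is the per-hit E-value ceiling; ``min_aln_len`` the
    minimum total repeat span (aa) required of multi-repeat calls;
    ``min_aln_rate`` the fraction of PSSM columns a hit must match to count
    as a full (rather than partial) repeat. ``max_repeat_gap`` is the
    largest residue gap between consecutive repeats of one tandem array.
    """

    evalue_max: float = 1e-10
    min_aln_len: int = 100
    min_aln_rate: float = 0.5
    max_repeat_gap: int = 30

    def __post_init__(self) -> None:
        if self.evalue_max <= 0 or self.min_aln_len <= 0 or self.min_aln_rate <= 0:
            raise ValueError("scan thresholds must be positive")


# ---------------------------------------------------------------------------
# model construction


def build_pssm(aligned: list[SequenceRecord], pseudocount: float = 0.5,
               background: np.ndarray | None = None) -> RepeatPSSM:
    """Build a log-odds PSSM (bits) from an ungapped repeat alignment."""
    width = len(aligned[0].residues)
    if any(len(r.residues) != width for r in aligned):
        raise ValueError("alignment rows differ in length")
    counts = np.zeros((20, width))
    for rec in aligned:
        for j, aa in enumerate(rec.residues):
            if aa not in _AA_INDEX:
                raise ValueError(f"non-standard residue {aa!r} in {rec.id}")
            counts[_AA_INDEX[aa], j] += 1
    if background is None:
        background = np.full(20, 1 / 20)
    # pseudocounts regularize the scoring matrix only; the emission
    # probabilities stay the raw column frequencies of the alignment
    smoothed = (counts + pseudocount) / (counts.sum(axis=0) + 20 * pseudocount)
    log_odds = np.log2(smoothed / background[:, None])
    probs = counts / counts.sum(axis=0)
    return RepeatPSSM(width=width, log_odds=log_odds, background=background,
                      bit_threshold=0.0, probs=probs)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-amino-acid character {exc.args[0]!r}") from None


def _window_scores(encoded: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window of the PSSM width; empty array if none fit."""
    width = log_odds.shape[1]
    n = encoded.size - width + 1
    if n <= 0:
        return np.empty(0)
    per_pos = log_odds[encoded, :]  # L x width
    idx = np.arange(n)[:, None] + np.arange(width)[None, :]
    cols = np.arange(width)[None, :]
    return per_pos[idx, cols].sum(axis=1)


def calibrate_pssm(pssm: RepeatPSSM, seed: int = 0, n_decoys: int = 400,
                   decoy_len: int = 500, pass_rate: float = 1e-4,
                   tail_fraction: float = 0.01) -> RepeatPSSM:
    """Set the bit threshold and Gumbel E-value parameters from decoys.

    Decoys are i.i.d. draws from the background composition; the threshold
    is the (1 - pass_rate/10) quantile of decoy window scores, so decoy
    windows pass at a rate well under ``pass_rate``. The Gumbel location
    and scale are fit to the upper ``tail_fraction`` of decoy scores
    (exponential excess over the tail threshold), which calibrates the
    survival function where E-values are actually evaluated rather than in
    the bulk of the null distribution.
    """
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_decoys):
        seq = rng.choice(20, size=decoy_len, p=pssm.background)
        scores.append(_window_scores(seq, pssm.log_odds))
    scores = np.concatenate(scores)
    threshold = float(np.quantile(scores, 1 - pass_rate / 10))
    u = float(np.quantile(scores, 1 - tail_fraction))
    excess = scores[scores > u] - u
    scale = float(excess.mean())
    # choose loc so that exp(-(u - loc)/scale) = tail_fraction
    loc = u + scale * np.log(tail_fraction)
    return RepeatPSSM(width=pssm.width, log_odds=pssm.log_odds,
                      background=pssm.background, bit_threshold=threshold,
                      probs=pssm.probs, gumbel=(float(loc), float(scale)))


_DATA = resources.files("familyscan") / "data"


def packaged_repeat_alignment() -> list[SequenceRecord]:
    with resources.as_file(_DATA / "myb_repeat_alignment.synthetic.fasta") as p:
        return read_fasta(p)


def load_packaged_pssm() -> RepeatPSSM:
    """The packaged, pre-calibrated repeat model."""
    raw = json.loads((_DATA / "myb_repeat_pssm.json").read_text())
    return RepeatPSSM(
        width=raw["width"],
        log_odds=np.array(raw["log_odds"]),
        background=np.array(raw["background"]),
        bit_threshold=raw["bit_threshold"],
        probs=np.array(raw["probs"]),
        gumbel=tuple(raw["gumbel"]),
    )


# ---------------------------------------------------------------------------
# scanning


def scan_repeats(protein: SequenceRecord, pssm: RepeatPSSM,
                 config: ScanConfig = ScanConfig()) -> list[MybRepeatHit]:
    """All non-overlapping repeat hits in one protein.

    Every window is scored; windows at or above the calibrated bit threshold
    and within the E-value ceiling are resolved greedily by descending score
    (ties by leftmost start) into a non-overlapping set.
    """
    encoded = _encode(protein.residues)
    scores = _window_scores(encoded, pssm.log_odds)
    if scores.size == 0:
        return []
    n_windows = scores.size
    candidate_idx = np.flatnonzero(scores >= pssm.bit_threshold)
    order = sorted(candidate_idx, key=lambda i: (-scores[i], i))
    taken: list[tuple[int, int]] = []
    hits: list[MybRepeatHit] = []
    per_pos = pssm.log_odds[encoded, :]
    for i in order:
        ev = pssm.window_evalue(float(scores[i]), n_windows)
        if ev > config.evalue_max:
            continue
        s, e = i, i + pssm.width - 1  # 0-based
        if any(s <= te and ts <= e for ts, te in taken):
            continue
        taken.append((s, e))
        window_cols = per_pos[np.arange(s, e + 1), np.arange(pssm.width)]
        matched = int(np.count_nonzero(window_cols > 0))
        hits.append(
            MybRepeatHit(protein_id=protein.id, start=s + 1, end=e + 1,
                         bits=float(scores[i]), evalue=ev, matched_columns=matched)
        )
    hits.sort(key=lambda h: h.start)
    return hits


def classify_subfamily(hits: list[MybRepeatHit], protein_len: int,
                       config: ScanConfig = ScanConfig(),
                       pssm_width: int | None = None) -> MybClassification:
    """Subfamily call from the retained hits of one protein.

    A hit is a full repeat when it matches more than ``min_aln_rate`` of the
    PSSM columns; weaker hits are partial. Repeats separated by more than
    ``max_repeat_gap`` residues are counted as separate arrays, and the call
    uses the largest array (distant singletons stay singletons). Mapping:
    1 full -> 1R, 2 -> R2R3, 3 -> 3R, 4 -> 4R, >=5 -> other (count kept),
    0 full with partials -> partial, nothing -> other.
    """
    hits = sorted(hits, key=lambda h: h.start)
    for a, b in zip(hits, hits[1:]):
        if b.start <= a.end:
            raise ValueError("hits must be non-overlapping and sorted")
    width = pssm_width or (hits[0].end - hits[0].start + 1 if hits else 0)
    full = [h for h in hits
            if width and h.matched_columns / width > config.min_aln_rate]
    n_partial = len(hits) - len(full)

    # largest tandem array among full repeats
    best_array = 0
    run = 0
    prev_end = None
    for h in full:
        if prev_end is not None and h.start - prev_end - 1 <= config.max_repeat_gap:
            run += 1
        else:
            run = 1
        best_array = max(best_array, run)
        prev_end = h.end
    n_repeats = best_array

    if n_repeats >= 2:
        span = full[-1].end - full[0].start + 1
        if span <= config.min_aln_len:
            raise ValueError(
                f"multi-repeat call spans {span} aa <= min_aln_len {config.min_aln_len}"
            )
    subfamily = {1: "1R", 2: "R2R3", 3: "3R", 4: "4R"}.get(n_repeats)
    if subfamily is None:
        if n_repeats >= 5:
            subfamily = "other"
        elif n_partial >= 1:
            subfamily = "partial"
        else:
            subfamily = "other"
    pid = hits[0].protein_id if hits else ""
    return MybClassification(protein_id=pid, n_repeats=n_repeats,
                             n_partial=n_partial, subfamily=subfamily, hits=hits)


def classify_proteome(proteins: list[SequenceRecord], pssm: RepeatPSSM,
                      config: ScanConfig = ScanConfig()) -> list[MybClassification]:
    """Scan and classify every protein; proteins with no hits are 'other'."""
    out = []
    for prot in proteins:
        hits = scan_repeats(prot, pssm, config)
        cls = classify_subfamily(hits, len(prot), config, pssm_width=pssm.width)
        cls.protein_id = prot.id
        out.append(cls)
    return out


def assign_names(classified: list[MybClassification], annotation: GenomeAnnotation,
                 prefix: str = "MYB") -> list[MybClassification]:
    """Name family members prefix+1..N by chromosome order then start.

    Ties on (chromosome, start) break by gene id lexicographically, so the
    numbering is stable across runs.
    """
    by_id = annotation.genes_by_id()
    order = annotation.chromosome_order
    keyed = []
    for cls in classified:
        gene = by_id.get(cls.protein_id)
        if gene is None:
            raise ValueError(f"protein {cls.protein_id} has no gene in the annotation")
        keyed.append(((order[gene.chromosome], gene.start, gene.id), cls))
    keyed.sort(key=lambda kv: kv[0])
    for i, (_, cls) in enumerate(keyed, start=1):
        cls.assigned_name = f"{prefix}{i}"
    return [cls for _, cls in keyed]
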