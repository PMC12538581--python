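"""Promoter predictions: external-table ingestion, a built-in σ70 PWM scanner,
and the exponential score weighting.

Predictions normally come from an external machine-learning promoter predictor
that emits a probability-like score in [0, 1] per hit; that score is treated
as a proxy for promoter strength.  A self-contained consensus position-weight-
matrix scanner for the bacterial σ70 −35/−10 two-box architecture is provided
as a fallback so the pipeline runs without any external tool.

The weighting places disproportionate emphasis on high-scoring predictions:

    w(s) = exp(s),   s ∈ [0, 1]

so a single predicted promoter of score 0.921 contributes exp(0.921) ≈ 2.51
to the cumulative score of its region.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_model import AnnotatedGenome, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.5

TABLE_COLUMNS = ["strand", "position", "type", "sequence", "score"]


@dataclass
class PromoterPrediction:
    """One predicted promoter, on the forward coordinate frame.

    ``start``/``end`` are the 0-based half-open footprint of the motif in
    forward coordinates regardless of strand; ``motif_seq`` is the motif in
    reading orientation (i.e. reverse-complemented relative to the forward
    sequence for − strand hits).
    """

    strand: str
    start: int
    end: int
    motif_seq: str
    score: float
    source: str = "external_table"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.end - self.start != len(self.motif_seq):
            raise ValueError("footprint length does not match motif sequence")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class WeightingScheme:
    """Monotone, convex transform of raw prediction scores.

    Only the exponential kind is defined: w(s) = exp(s).  It satisfies
    w(0) = 1 and strictly favors high-scoring predictions.
    """

    kind: str = "exponential"

    def weight(self, s: float) -> float:
        return weight_score(s, self)


def weight_score(s: float, scheme: WeightingScheme | None = None) -> float:
    """Exponentially weighted prediction score, w(s) = exp(s)."""
    scheme = scheme or WeightingScheme()
    if scheme.kind != "exponential":
        raise ValueError(f"unknown weighting scheme {scheme.kind!r}")
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"score {s} outside [0, 1]")
    return math.exp(s)


# ---------------------------------------------------------------------------
# external prediction tables
#
# Documented column order: strand, position (1-based), type/motif label,
# sequence, score.  Tab- or comma-separated; a header line is tolerated and
# auto-detected by a non-numeric score field.  Minus-strand positions are
# given on the reverse-complement frame (1-based from the 3' end of the
# forward strand) and are reflected into forward coordinates on read.


def _reflect_minus(position_1based: int, motif_len: int, genome_length: int) -> tuple[int, int]:
    end = genome_length - (position_1based - 1)
    return end - motif_len, end


def parse_predictions_table(
    path: str | Path,
    genome_length: int,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> list[PromoterPrediction]:
    """Read a predictor output table into forward-frame predictions.

    Rows scoring below ``threshold`` are dropped; rows with a score outside
    [0, 1] are rejected with a logged warning; a position outside the genome
    or an unparsable line is a hard error naming the line number.
    """
    preds: list[PromoterPrediction] = []
    with open(path, newline="") as fh:
        sample = fh.readline()
        delim = "\t" if "\t" in sample else ","
        fh.seek(0)
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not row or not "".join(row).strip():
                continue
            if len(row) == 4:  # motif-type column omitted
                row = [row[0], row[1], "", row[2], row[3]]
            if len(row) < 5:
                raise ValueError(f"{path}: line {lineno}: expected 4 or 5 fields")
            strand_s, pos_s, _mtype, seq, score_s = (c.strip() for c in row[:5])
            try:
                score = float(score_s)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}: line {lineno}: unparsable score {score_s!r}")
            try:
                pos = int(pos_s)
                strand = {"+": "+", "-": "-", "1": "+", "-1": "-"}[strand_s]
            except (ValueError, KeyError):
                raise ValueError(f"{path}: line {lineno}: unparsable strand/position")
            if not (0.0 <= score <= 1.0):
                logger.warning(
                    "%s: line %d: score %s outside [0, 1]; row rejected", path, lineno, score
                )
                continue
            seq = seq.upper()
            if strand == "+":
                start, end = pos - 1, pos - 1 + len(seq)
            else:
                start, end = _reflect_minus(pos, len(seq), genome_length)
            if start < 0 or end > genome_length:
                raise ValueError(
                    f"{path}: line {lineno}: position outside genome ({start}, {end})"
                )
            if score < threshold:
                continue
            preds.append(
                PromoterPrediction(strand, start, end, seq, score, source="external_table")
            )
    return preds


def write_predictions_table(
    preds: Sequence[PromoterPrediction], path: str | Path, genome_length: int
) -> None:
    """Write predictions in the table dialect read by :func:`parse_predictions_table`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TABLE_COLUMNS)
        for p in preds:
            if p.strand == "+":
                pos = p.start + 1
            else:
                pos = genome_length - p.end + 1
            w.writerow([p.strand, pos, "promoter", p.motif_seq, f"{p.score:g}"])


# ---------------------------------------------------------------------------
# built-in σ70 consensus PWM scanner

_BASES = "ACGT"
_CONSENSUS_35 = "TTGACA"
_CONSENSUS_10 = "TATAAT"


def _consensus_pwm(consensus: str, match_p: float = 0.8) -> np.ndarray:
    """(4, w) column-stochastic matrix concentrated on the consensus base."""
    off = (1.0 - match_p) / 3.0
    pwm = np.full((4, len(consensus)), off)
    for j, b in enumerate(consensus):
        pwm[_BASES.index(b), j] = match_p
    return pwm


@dataclass
class PwmModel:
    """Two-box σ70 promoter model: −35 and −10 PWMs joined by a spacer.

    The summed log-odds of both boxes (vs. uniform background) is mapped to a
    probability-like score in [0, 1] through a logistic with the given
    midpoint and scale, calibrated so the exact consensus scores > 0.99 and a
    random window scores far below 0.1 — keeping built-in scores commensurate
    with external probability scores.
    """

    minus35: np.ndarray = field(default_factory=lambda: _consensus_pwm(_CONSENSUS_35))
    minus10: np.ndarray = field(default_factory=lambda: _consensus_pwm(_CONSENSUS_10))
    spacer_range: tuple[int, int] = (15, 19)
    logistic_midpoint: float = 7.0
    logistic_scale: float = 1.0

    def __post_init__(self) -> None:
        for m in (self.minus35, self.minus10):
            if not np.allclose(m.sum(axis=0), 1.0):
                raise ValueError("PWM columns must sum to 1")
        if self.spacer_range[0] > self.spacer_range[1]:
            raise ValueError("spacer_min must be <= spacer_max")

    def log_odds(self, pwm: np.ndarray) -> np.ndarray:
        """(5, w) log-odds lookup; the 5th row (ambiguous base) is neutral."""
        lo = np.zeros((5, pwm.shape[1]))
        lo[:4] = np.log(pwm / 0.25)
        return lo

    def scale_score(self, log_odds_sum: float | np.ndarray) -> float | np.ndarray:
        x = (log_odds_sum - self.logistic_midpoint) / self.logistic_scale
        return 1.0 / (1.0 + np.exp(-x))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"consensus35\t{_pwm_consensus_string(self.minus35)}\n")
            fh.write(f"consensus10\t{_pwm_consensus_string(self.minus10)}\n")
            fh.write(f"match_p\t{self.minus35.max(axis=0)[0]:g}\n")
            fh.write(f"spacer_min\t{self.spacer_range[0]}\n")
            fh.write(f"spacer_max\t{self.spacer_range[1]}\n")
            fh.write(f"logistic_midpoint\t{self.logistic_midpoint:g}\n")
            fh.write(f"logistic_scale\t{self.logistic_scale:g}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PwmModel":
        kv = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    k, v = line.rstrip("\n").split("\t")
                    kv[k] = v
        p = float(kv.get("match_p", 0.8))
        return cls(
            minus35=_consensus_pwm(kv.get("consensus35", _CONSENSUS_35), p),
            minus10=_consensus_pwm(kv.get("consensus10", _CONSENSUS_10), p),
            spacer_range=(int(kv.get("spacer_min", 15)), int(kv.get("spacer_max", 19))),
            logistic_midpoint=float(kv.get("logistic_midpoint", 7.0)),
            logistic_scale=float(kv.get("logistic_scale", 1.0)),
        )


def _pwm_consensus_string(pwm: np.ndarray) -> str:
    return "".join(_BASES[i] for i in pwm.argmax(axis=0))


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        out[arr == ord(b)] = i
    return out


def _box_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Sliding-window log-odds sums of one box over an encoded sequence."""
    w = lo.shape[1]
    if len(codes) < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lo[windows, np.arange(w)].sum(axis=1)


def scan_builtin_pwm(
    genome: AnnotatedGenome | str,
    model: PwmModel | None = None,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    both_strands: bool = True,
) -> list[PromoterPrediction]:
    """Scan for two-box σ70 promoter placements above ``threshold``.

    Every (−35 position, spacer) placement within the allowed spacer range is
    scored independently; each placement passing the threshold yields one
    prediction whose footprint covers the full −35..−10 span.  Deterministic.
    """
    model = model or PwmModel()
    seq = genome if isinstance(genome, str) else genome.sequence
    seq = seq.upper()
    L = len(seq)
    lo35 = model.log_odds(model.minus35)
    lo10 = model.log_odds(model.minus10)
    w35, w10 = lo35.shape[1], lo10.shape[1]
    hits: list[PromoterPrediction] = []
    strands = [("+", seq)] + ([("-", reverse_complement(seq))] if both_strands else [])
    for strand, s in strands:
        codes = _encode(s)
        b35 = _box_scores(codes, lo35)
        b10 = _box_scores(codes, lo10)
        for spacer in range(model.spacer_range[0], model.spacer_range[1] + 1):
            flen = w35 + spacer + w10
            if L < flen:
                continue
            n = L - flen + 1
            total = b35[:n] + b10[w35 + spacer : w35 + spacer + n]
            scores = model.scale_score(total)
            for i in np.nonzero(scores >= threshold)[0]:
                if strand == "+":
                    start, end = int(i), int(i) + flen
                else:
                    start, end = L - (int(i) + flen), L - int(i)
                hits.append(
                    PromoterPrediction(
                        strand=strand,
                        start=start,
                        end=end,
                        motif_seq=s[int(i) : int(i) + flen],
                        score=float(min(scores[i], 1.0)),
                        source="builtin_pwm",
                    )
                )
    hits.sort(key=lambda p: (p.start, p.end, p.strand))
    return hits
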