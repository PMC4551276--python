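"""Score samples, paired samples, and discrete score distributions.

The input boundary of the toolkit is two sets of similarity scores: genuine
(positive-class) scores ``G`` obtained by matching samples of the same subject,
and impostor (negative-class) scores ``I`` from matching different subjects.
All downstream metrics operate on the empirical discrete distribution of those
scores over a shared support, with *top-down* cumulatives

    C_i(s) = sum_{tau >= s} P_i(tau),   i in {G, I},

so that ``C_G`` is the true accept rate (TAR) and ``C_I`` the false accept
rate (FAR) when the acceptance threshold is placed at ``s``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ScoreSample",
    "PairedScoreSample",
    "DiscreteScoreDistribution",
    "load_scores",
    "load_scores_split",
    "load_paired_scores",
    "build_distributions",
]

GENUINE_LABELS = frozenset({"genuine", "g", "gen", "1", "pos", "positive"})
IMPOSTOR_LABELS = frozenset({"impostor", "i", "imp", "0", "neg", "negative"})


def _as_score_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} scores must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} set empty: at least one {name} score is required")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"{name} score at position {bad} is not finite: {arr[bad]!r}")
    return arr


@dataclass(frozen=True)
class ScoreSample:
    """A pair of raw score sets: genuine scores G and impostor scores I.

    Scores are stored in file/entry order; ordering matters for paired
    two-algorithm analyses where scores co-vary by ordinal position.
    """

    genuine: np.ndarray
    impostor: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genuine", _as_score_array(self.genuine, "genuine"))
        object.__setattr__(self, "impostor", _as_score_array(self.impostor, "impostor"))

    @property
    def n_genuine(self) -> int:
        return self.genuine.size

    @property
    def n_impostor(self) -> int:
        return self.impostor.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreSample):
            return NotImplemented
        return (
            np.array_equal(self.genuine, other.genuine)
            and np.array_equal(self.impostor, other.impostor)
        )


@dataclass(frozen=True)
class PairedScoreSample:
    """Score sets of two algorithms A and B run on the same comparisons.

    Index ``j`` of A's genuine (impostor) list and index ``j`` of B's refer to
    the same underlying comparison, so the two scores co-vary.
    """

    sample_a: ScoreSample
    sample_b: ScoreSample

    def __post_init__(self) -> None:
        a, b = self.sample_a, self.sample_b
        if a.n_genuine != b.n_genuine:
            raise ValueError(
                "paired samples must have equal genuine counts: "
                f"A has {a.n_genuine}, B has {b.n_genuine}"
            )
        if a.n_impostor != b.n_impostor:
            raise ValueError(
                "paired samples must have equal impostor counts: "
                f"A has {a.n_impostor}, B has {b.n_impostor}"
            )

    @property
    def n_genuine(self) -> int:
        return self.sample_a.n_genuine

    @property
    def n_impostor(self) -> int:
        return self.sample_a.n_impostor


@dataclass(frozen=True)
class DiscreteScoreDistribution:
    """Empirical distributions of both classes on a shared discrete support.

    ``support`` is strictly increasing; ``p_genuine``/``p_impostor`` are the
    per-value probabilities and ``c_genuine``/``c_impostor`` the top-down
    cumulatives (fraction of scores at or above each support value). The
    cumulative beyond the largest support value is 0 by convention.
    """

    support: np.ndarray
    p_genuine: np.ndarray
    p_impostor: np.ndarray
    c_genuine: np.ndarray = field(default=None)  # type: ignore[assignment]
    c_impostor: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        pg = np.asarray(self.p_genuine, dtype=float)
        pi = np.asarray(self.p_impostor, dtype=float)
        if support.size == 0:
            raise ValueError("support must be non-empty")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if pg.shape != support.shape or pi.shape != support.shape:
            raise ValueError("probability arrays must match the support shape")
        if np.any(pg < 0) or np.any(pi < 0):
            raise ValueError("probabilities must be non-negative")
        for name, p in (("genuine", pg), ("impostor", pi)):
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} probabilities must sum to 1, got {p.sum()!r}")
        cg = self.c_genuine if self.c_genuine is not None else _topdown_cumulative(pg)
        ci = self.c_impostor if self.c_impostor is not None else _topdown_cumulative(pi)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "p_genuine", pg)
        object.__setattr__(self, "p_impostor", pi)
        object.__setattr__(self, "c_genuine", np.asarray(cg, dtype=float))
        object.__setattr__(self, "c_impostor", np.asarray(ci, dtype=float))

    @property
    def s_min(self) -> float:
        return float(self.support[0])

    @property
    def s_max(self) -> float:
        return float(self.support[-1])

    def next_value(self, index: int) -> float:
        """The next larger support value after ``support[index]`` (inf past the top)."""
        if index + 1 < self.support.size:
            return float(self.support[index + 1])
        return float("inf")


def _topdown_cumulative(p: np.ndarray) -> np.ndarray:
    # cumulate from s_max down to each s; C(s_min) = 1 exactly
    c = np.cumsum(p[::-1])[::-1]
    c[0] = 1.0
    return c


def _parse_score(token: str, row: int, path: Path) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"{path}, row {row}: non-numeric score {token!r}") from None
    if not np.isfinite(value):
        raise ValueError(f"{path}, row {row}: score is not finite: {token!r}")
    return value


def load_scores(path: str | Path, format: str = "auto", label: str = "") -> ScoreSample:
    """Read a score file into a validated :class:`ScoreSample`.

    The file holds delimited rows ``label,score`` (comma or tab), with labels
    designating genuine vs impostor (``genuine``/``impostor``, ``g``/``i``,
    ``1``/``0``, ...). Row order within each class is preserved. For a pair of
    one-score-per-line files (one per class) use :func:`load_scores_split`.
    """
    path = Path(path)
    if format not in {"auto", "labelled"}:
        raise ValueError(f"unknown format {format!r}")
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValueError(f"cannot read score file {path}: {exc}") from exc

    genuine: list[float] = []
    impostor: list[float] = []
    delimiter = "\t" if "\t" in text else ","
    reader = csv.reader(text.splitlines(), delimiter=delimiter)
    for row, fields in enumerate(reader, start=1):
        fields = [f.strip() for f in fields if f.strip()]
        if not fields or fields[0].startswith("#"):
            continue
        if len(fields) != 2:
            raise ValueError(
                f"{path}, row {row}: expected 'label{delimiter}score', got {fields!r}"
            )
        tag, token = fields[0].lower(), fields[1]
        value = _parse_score(token, row, path)
        if tag in GENUINE_LABELS:
            genuine.append(value)
        elif tag in IMPOSTOR_LABELS:
            impostor.append(value)
        else:
            raise ValueError(
                f"{path}, row {row}: unrecognized class label {fields[0]!r} "
                "(expected genuine/impostor)"
            )
    if not genuine:
        raise ValueError(f"{path}: genuine set empty")
    if not impostor:
        raise ValueError(f"{path}: impostor set empty")
    return ScoreSample(np.asarray(genuine), np.asarray(impostor), label=label or path.stem)


def _read_single_column(path: str | Path, role: str) -> np.ndarray:
    """Read a one-score-per-line file holding a single class."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValueError(f"cannot read score file {path}: {exc}") from exc
    scores: list[float] = []
    for row, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        scores.append(_parse_score(line, row, path))
    if not scores:
        raise ValueError(f"{path}: {role} set empty")
    return np.asarray(scores)


def load_scores_split(
    genuine_path: str | Path, impostor_path: str | Path, label: str = ""
) -> ScoreSample:
    """Read genuine and impostor scores from two one-score-per-line files."""
    g = _read_single_column(genuine_path, "genuine")
    i = _read_single_column(impostor_path, "impostor")
    return ScoreSample(g, i, label=label)


def load_paired_scores(
    path_a: str | Path, path_b: str | Path, format: str = "auto"
) -> PairedScoreSample:
    """Read two labelled score files with row-index pairing preserved.

    Row ``j`` of A's genuine (impostor) scores and row ``j`` of B's must come
    from the same underlying comparison; class sizes must therefore match.
    """
    a = load_scores(path_a, format=format, label=Path(path_a).stem)
    b = load_scores(path_b, format=format, label=Path(path_b).stem)
    return PairedScoreSample(a, b)


def build_distributions(
    sample: ScoreSample, decimals: int | None = None
) -> DiscreteScoreDistribution:
    """Discretize a score sample onto a shared support.

    ``decimals=None`` (distinct-values mode) uses every distinct observed score
    as a support point — the faithful discrete support for real-valued scores.
    ``decimals=d`` first rounds every score to ``d`` decimal digits, mimicking
    score systems that convert to fixed-precision integers.
    """
    if decimals is not None:
        if decimals < 0:
            raise ValueError(f"decimals must be >= 0, got {decimals}")
        g = np.round(sample.genuine, decimals)
        i = np.round(sample.impostor, decimals)
    else:
        g, i = sample.genuine, sample.impostor

    gv, gc = np.unique(g, return_counts=True)
    iv, ic = np.unique(i, return_counts=True)
    support = np.union1d(gv, iv)
    # cumulatives from integer counts (not float cumsum) so that ratios like
    # C(s) = #{scores >= s} / N are as exact as the division allows
    pg = np.zeros(support.size)
    pi = np.zeros(support.size)
    cg = np.zeros(support.size, dtype=np.int64)
    ci = np.zeros(support.size, dtype=np.int64)
    pg[np.searchsorted(support, gv)] = gc / g.size
    pi[np.searchsorted(support, iv)] = ic / i.size
    cg[np.searchsorted(support, gv)] = gc
    ci[np.searchsorted(support, iv)] = ic
    c_genuine = np.cumsum(cg[::-1])[::-1] / g.size
    c_impostor = np.cumsum(ci[::-1])[::-1] / i.size
    return DiscreteScoreDistribution(support, pg, pi, c_genuine, c_impostor)
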