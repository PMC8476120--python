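"""Cluster-size transition matrices, predicted stochastic model and rates.

Measured matrices tally frame-to-frame changes of active-region occupancy.
Two normalisations are supported:

``conditional``
    Probability of moving from size i to size j *given that the size
    changed*: the diagonal is zero and every observed row sums to 1.  This
    is the layout used for published transition tables.
``per_frame``
    Unconditional per-frame probability: transition counts divided by all
    observed frame pairs starting at size i (including i -> i dwells).
    This is the scale on which the kinetic model lives -- the single-head
    detachment probability ``Pd = 1 - exp(-k_T [ATP] t)`` and the
    attachment probability ``Pa`` are per-frame quantities -- so model
    comparison and parameter recovery use this mode.

The predicted model matrix takes ``p[i][j] = Pa^(j-i)`` above the diagonal
and ``p[i][j] = C(i, i-j) Pd^(i-j)`` below it (optionally with the
``(1-Pd)^j`` survival factor of the heads that remain, the full binomial
law).  Complete-collapse probabilities extracted from the first column can
be inverted back to effective detachment rate constants.
"""

from __future__ import annotations  # noqa: F401  (postponed annotation evaluation)

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "KineticParams",
    "TransitionCounts",
    "TransitionMatrix",
    "count_transitions",
    "pool_counts",
    "to_matrix",
    "detachment_probability",
    "predicted_matrix",
    "estimate_pa",
    "collapse_curve",
    "invert_collapse_to_rate",
    "compare_collapse_to_prediction",
    "read_transition_table_excel",
    "write_transition_table_csv",
]


@dataclass(frozen=True)
class KineticParams:
    """ATP-binding kinetics that set the per-frame detachment probability."""

    k_T: float = 1.9     # second-order ATP-binding rate constant, 1/(uM s)
    atp_uM: float = 0.1  # ATP concentration, uM
    frame_s: float = 0.3 # frame duration, s

    def __post_init__(self) -> None:
        if self.k_T <= 0 or self.atp_uM <= 0 or self.frame_s <= 0:
            raise ValueError("kinetic parameters must all be > 0")

    @property
    def detachment_rate_s(self) -> float:
        """First-order detachment rate constant k_T * [ATP] (1/s)."""
        return self.k_T * self.atp_uM


def detachment_probability(k: KineticParams) -> float:
    """Per-frame single-head detachment probability 1 - exp(-k_T [ATP] t)."""
    return float(1.0 - math.exp(-k.k_T * k.atp_uM * k.frame_s))


@dataclass
class TransitionCounts:
    """Raw transition tallies, with the per-kymograph breakdown retained.

    ``counts[i, j]`` is the number of observed one-frame transitions from
    size i (1..n_max) to size j (0..n_max) with i != j; ``exposure[i]`` is
    the number of observed consecutive frame pairs starting at size i
    (including i -> i dwells).  Pairs containing a missing value or a size
    above ``n_max`` are discarded.
    """

    n_max: int
    counts: np.ndarray
    exposure: np.ndarray
    per_source: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


def _tally(series_list: Iterable[np.ndarray], n_max: int):
    counts = np.zeros((n_max + 1, n_max + 1), dtype=np.int64)
    exposure = np.zeros(n_max + 1, dtype=np.int64)
    for s in series_list:
        a = np.asarray(s, dtype=np.float64)
        for t in range(a.size - 1):
            i, j = a[t], a[t + 1]
            if not (np.isfinite(i) and np.isfinite(j)):
                continue
            i, j = int(round(i)), int(round(j))
            if not (1 <= i <= n_max) or not (0 <= j <= n_max):
                continue
            exposure[i] += 1
            if i != j:
                counts[i, j] += 1
    return counts, exposure


def count_transitions(
    series: Sequence[np.ndarray] | Mapping[str, Sequence[np.ndarray]],
    n_max: int = 6,
) -> TransitionCounts:
    """Tally one-frame transitions from per-region count series.

    ``series`` is either a flat list of count arrays (pooled under a single
    source) or a mapping ``kymograph_id -> list of count arrays`` so that
    per-kymograph SEMs can be formed later.  Missing values (NaN) break
    pairs; sizes above ``n_max`` are discarded; i -> i pairs enter the
    exposure only.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if isinstance(series, Mapping):
        groups = {str(k): list(v) for k, v in series.items()}
    else:
        groups = {"pooled": list(series)}
    per_source = {}
    total_c = np.zeros((n_max + 1, n_max + 1), dtype=np.int64)
    total_e = np.zeros(n_max + 1, dtype=np.int64)
    for sid, group in groups.items():
        c, e = _tally(group, n_max)
        per_source[sid] = (c, e)
        total_c += c
        total_e += e
    return TransitionCounts(n_max=n_max, counts=total_c, exposure=total_e,
                            per_source=per_source)


def pool_counts(parts: Sequence[TransitionCounts]) -> TransitionCounts:
    """Concatenate transition counts from several datasets (simple pooling)."""
    if not parts:
        raise ValueError("nothing to pool")
    n_max = parts[0].n_max
    if any(p.n_max != n_max for p in parts):
        raise ValueError("all parts must share n_max")
    counts = sum(p.counts for p in parts)
    exposure = sum(p.exposure for p in parts)
    per_source: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for k, p in enumerate(parts):
        for sid, v in p.per_source.items():
            key = sid if sid not in per_source else f"{k}:{sid}"
            per_source[key] = v
    return TransitionCounts(n_max=n_max, counts=counts, exposure=exposure,
                            per_source=per_source)


@dataclass
class TransitionMatrix:
    """Transition probabilities with zero diagonal.

    ``mode`` is one of ``conditional`` (rows sum to 1 given a change),
    ``per_frame`` (unconditional per-frame probabilities) or ``model``
    (computed from Pa/Pd rather than measured).  ``row_totals`` holds the
    denominator counts; rows with no observations are all-zero.  ``sem`` is
    the standard error of each cell across contributing kymographs (NaN
    when fewer than two kymographs contribute).
    """

    n_max: int
    p: np.ndarray
    row_totals: np.ndarray
    sem: np.ndarray
    normalised: bool
    mode: str

    def first_column(self) -> np.ndarray:
        return self.p[1:, 0].copy()

    def superdiagonal(self) -> np.ndarray:
        return np.array([self.p[i, i + 1] for i in range(1, self.n_max)])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.p[1:, :], index=range(1, self.n_max + 1),
                          columns=range(0, self.n_max + 1))
        df.index.name = "start_size"
        df.columns.name = "final_size"
        return df


def _probabilities(counts: np.ndarray, exposure: np.ndarray, mode: str,
                   n_max: int) -> tuple[np.ndarray, np.ndarray]:
    if mode == "conditional":
        denom = counts.sum(axis=1).astype(np.float64)
    elif mode == "per_frame":
        denom = exposure.astype(np.float64)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = np.zeros_like(counts, dtype=np.float64)
    rows = denom > 0
    p[rows] = counts[rows] / denom[rows, None]
    return p, denom


def to_matrix(c: TransitionCounts, mode: str = "conditional") -> TransitionMatrix:
    """Normalise transition counts into a TransitionMatrix.

    Conditional rows with at least one observation sum to 1; the diagonal is
    always zero.  Cell SEMs are computed across the kymographs whose rows
    carry observations.
    """
    if c.n_transitions == 0:
        raise ValueError("no transitions observed")
    p, denom = _probabilities(c.counts, c.exposure, mode, c.n_max)
    sem = np.full_like(p, np.nan)
    if len(c.per_source) >= 2:
        per = []
        per_rows = []
        for counts_s, exp_s in c.per_source.values():
            ps, denom_s = _probabilities(counts_s, exp_s, mode, c.n_max)
            per.append(ps)
            per_rows.append(denom_s > 0)
        per = np.stack(per)          # (S, n_max+1, n_max+1)
        per_rows = np.stack(per_rows)  # (S, n_max+1)
        for i in range(1, c.n_max + 1):
            contributing = per_rows[:, i]
            m = int(contributing.sum())
            if m >= 2:
                vals = per[contributing, i, :]
                sem[i, :] = vals.std(axis=0, ddof=1) / np.sqrt(m)
    return TransitionMatrix(n_max=c.n_max, p=p, row_totals=denom, sem=sem,
                            normalised=(mode == "conditional"), mode=mode)


def predicted_matrix(
    pa: float,
    pd: float,
    n_max: int = 6,
    normalise: bool = False,
    full_binomial: bool = False,
) -> TransitionMatrix:
    """Model transition matrix from the attachment/detachment probabilities.

    Above the diagonal ``p[i][j] = pa**(j-i)`` (j-i heads joining in one
    frame); below it ``p[i][j] = C(i, i-j) * pd**(i-j)``, i.e. the number of
    ways n = i-j heads can leave times the n-th power of the single-head
    detachment probability.  ``full_binomial=True`` multiplies in the
    ``(1-pd)**j`` probability that the remaining j heads stay put, turning
    each row's detachment block into a proper binomial law.
    """
    if not (0.0 < pa < 1.0) or not (0.0 < pd < 1.0):
        raise ValueError("pa and pd must lie in (0, 1)")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    p = np.zeros((n_max + 1, n_max + 1), dtype=np.float64)
    for i in range(1, n_max + 1):
        for j in range(0, n_max + 1):
            if j == i:
                continue
            if j > i:
                p[i, j] = pa ** (j - i)
            else:
                n = i - j
                p[i, j] = math.comb(i, n) * pd ** n
                if full_binomial:
                    p[i, j] *= (1.0 - pd) ** j
    normalised = False
    if normalise:
        rowsums = p.sum(axis=1)
        rows = rowsums > 0
        p[rows] /= rowsums[rows, None]
        normalised = True
    return TransitionMatrix(
        n_max=n_max, p=p, row_totals=np.zeros(n_max + 1),
        sem=np.full_like(p, np.nan), normalised=normalised, mode="model",
    )


def estimate_pa(m: TransitionMatrix, pd: float | None = None) -> float:
    """Attachment probability: mean of the first superdiagonal.

    The plain (paper-style) estimate is the unweighted mean of
    ``p[i][i+1]`` over rows with observations.  For a ``per_frame`` matrix
    the expected superdiagonal under the stochastic model is
    ``pa * (1-pd)**i`` -- a head can only be seen joining when none of the i
    bound heads left in the same frame -- so passing ``pd`` divides each
    entry by its survival factor and returns a bias-corrected estimate.
    """
    vals = []
    for i in range(1, m.n_max):
        # a row counts as observed when it carries probability mass or a
        # recorded denominator (tables read from published files have no
        # row totals)
        if m.row_totals[i] > 0 or m.p[i].any():
            v = m.p[i, i + 1]
            if pd is not None:
                v /= (1.0 - pd) ** i
            vals.append(v)
    if not vals:
        raise ValueError("no observed attachment transitions")
    return float(np.mean(vals))


def collapse_curve(m: TransitionMatrix) -> list[tuple[int, float, float]]:
    """First-column extraction: complete-collapse probability per start size.

    Returns ``(i, p[i][0], sem)`` for each starting size; the SEM is NaN when
    fewer than two kymographs contribute (single-kymograph input).
    """
    return [(i, float(m.p[i, 0]), float(m.sem[i, 0]))
            for i in range(1, m.n_max + 1)]


def invert_collapse_to_rate(p_collapse: float, i: int, frame_s: float) -> float:
    """Invert a complete-collapse probability into a detachment rate (1/s).

    Reverses the model construction ``p_collapse = Pd**i`` with
    ``Pd = 1 - exp(-k t)``: returns ``-ln(1 - p_collapse**(1/i)) / t``.
    """
    if not (0.0 < p_collapse < 1.0):
        raise ValueError("p_collapse must lie in (0, 1)")
    if i < 1:
        raise ValueError("cluster size i must be >= 1")
    if frame_s <= 0:
        raise ValueError("frame_s must be > 0")
    pd_eff = p_collapse ** (1.0 / i)
    return float(-math.log(1.0 - pd_eff) / frame_s)


def compare_collapse_to_prediction(
    measured: TransitionMatrix,
    pd: float,
    min_row_exposure: int = 50,
    alpha: float = 1e-3,
) -> list[dict]:
    """Compare a measured per-frame collapse curve with the binomial law pd**i.

    For every starting size with at least ``min_row_exposure`` observed frame
    pairs (sparser rows are dominated by sampling noise and reported but not
    compared), returns the measured probability, the prediction, whether the
    measurement exceeds it, and the exact-binomial two-sided p-value of the
    measured collapse count under the predicted probability.
    """
    if measured.mode != "per_frame":
        raise ValueError("collapse comparison needs a per-frame matrix")
    out = []
    for i in range(1, measured.n_max + 1):
        n = int(round(measured.row_totals[i]))
        p_meas = float(measured.p[i, 0])
        p_pred = pd ** i
        k_obs = int(round(p_meas * n))
        entry = {
            "size": i,
            "exposure": n,
            "measured": p_meas,
            "predicted": p_pred,
            "compared": n >= min_row_exposure,
            "exceeds": p_meas > p_pred,
            "pvalue": float("nan"),
        }
        if n > 0:
            entry["pvalue"] = float(binomtest(k_obs, n, p_pred).pvalue)
            entry["consistent"] = entry["pvalue"] >= alpha
        out.append(entry)
    return out


def write_transition_table_csv(m: TransitionMatrix, path: str | Path) -> None:
    """Write a matrix in the published source-data layout (rows = start size)."""
    m.to_dataframe().to_csv(path)


def read_transition_table_excel(
    path: str | Path,
    sheet: int | str = 0,
    n_max: int = 6,
) -> TransitionMatrix:
    """Read a published transition table from an Excel source-data sheet.

    The reader locates the first rectangular numeric block of shape
    ``(n_max, n_max + 1)`` -- rows are starting sizes 1..n_max, columns final
    sizes 0..n_max -- ignoring any surrounding labels.  Returns a
    conditional TransitionMatrix with unknown row totals and no SEMs.
    """
    raw = pd.read_excel(path, sheet_name=sheet, header=None)
    num = raw.apply(pd.to_numeric, errors="coerce")
    num = num.dropna(axis=0, how="all").dropna(axis=1, how="all")
    arr = num.to_numpy(dtype=np.float64)
    rows, cols = arr.shape
    for r0 in range(rows - n_max + 1):
        for c0 in range(cols - n_max):
            block = arr[r0:r0 + n_max, c0:c0 + n_max + 1]
            if np.isfinite(block).all():
                # a transition table has a zero diagonal (cell [i-1, i])
                diag = np.array([block[i - 1, i] for i in range(1, n_max + 1)])
                if np.allclose(diag, 0.0):
                    p = np.zeros((n_max + 1, n_max + 1))
                    p[1:, :] = block
                    return TransitionMatrix(
                        n_max=n_max, p=p, row_totals=np.zeros(n_max + 1),
                        sem=np.full_like(p, np.nan), normalised=True,
                        mode="conditional",
                    )
    raise ValueError(f"no {n_max} x {n_max + 1} transition block found in {path}")
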