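"""Recovery of systolic and diastolic pressure from an oscillation envelope.

Three stages, each usable on its own:

1. :func:`fit_stiffness` — semi-log regressions on the head and tail of the
   envelope recover the artery stiffness exponents: in the head (cuff well
   above systolic, artery collapsed throughout the beat) the amplitude is
   ``k1*exp(-a*P)``, in the tail (cuff below diastolic, artery distended
   throughout) it is ``k3*exp(+b*P)``.
2. :func:`predicted_envelope` — with the exponents fixed, each candidate
   (SBP, DBP) pair predicts a full envelope shape from the pressure–volume
   law and the cuff compliance.
3. :func:`estimate_pressures` — a grid search minimises the sum of squared
   differences between the amplitude-normalised observed and predicted
   envelopes; the normalisation cancels the unknown artery and cuff
   volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import ATM_MMHG, ArteryModel, CuffModel, artery_volume
from .simulate import Envelope

__all__ = [
    "StiffnessFit",
    "EstimationResult",
    "pulse_volume",
    "fit_stiffness",
    "predicted_envelope",
    "sum_of_squares",
    "estimate_pressures",
]

logger = logging.getLogger(__name__)


def pulse_volume(Pt, PP: float, artery: ArteryModel):
    """Artery volume swing (ml) over one pulse from the diastolic nadir.

    ``Pt`` is the transmural pressure at the diastolic nadir (mmHg) and
    ``PP`` the pulse pressure, so the swing spans ``[Pt, Pt + PP]``.  The
    three closed-form domain expressions are used:

    * Domain 1, ``Pt + PP < 0`` (fully collapsed):
      ``Va0*(exp(a*(Pt+PP)) - exp(a*Pt))``
    * Domain 2, ``Pt < 0 <= Pt + PP`` (swing straddles zero):
      ``Va0*(1 + a/b*(1 - exp(-b*(Pt+PP))) - exp(a*Pt))``
    * Domain 3, ``Pt >= 0`` (fully distended):
      ``Va0*a/b*(exp(-b*Pt) - exp(-b*(Pt+PP)))``

    They agree identically with ``artery_volume(Pt+PP) - artery_volume(Pt)``
    and are continuous across the domain boundaries; the swing is maximal
    for a nadir inside Domain 2.
    """
    if PP <= 0:
        raise ValueError(f"pulse pressure must be positive, got PP={PP}")
    Pt = np.asarray(Pt, dtype=float)
    a, b, Va0 = artery.a, artery.b, artery.Va0
    top = Pt + PP

    neg = np.minimum(Pt, 0.0)
    pos = np.maximum(Pt, 0.0)
    top_neg = np.minimum(top, 0.0)
    top_pos = np.maximum(top, 0.0)

    d1 = Va0 * (np.exp(a * top_neg) - np.exp(a * neg))
    d2 = Va0 * (1.0 + (a / b) * (1.0 - np.exp(-b * top_pos)) - np.exp(a * neg))
    d3 = Va0 * (a / b) * (np.exp(-b * pos) - np.exp(-b * top_pos))

    out = np.where(top < 0.0, d1, np.where(Pt < 0.0, d2, d3))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class StiffnessFit:
    """Diagnostics of the two semi-log envelope regressions."""

    a_hat: float
    b_hat: float
    slope_head: float
    slope_tail: float
    log_k1: float
    log_k3: float
    n_head: int
    n_tail: int
    head_indices: np.ndarray = field(repr=False)
    tail_indices: np.ndarray = field(repr=False)
    n_dropped: int = 0


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_stiffness(
    env: Envelope,
    head_fraction: float = 1.0 / 3.0,
    tail_fraction: float = 2.0 / 3.0,
    method: str = "height",
) -> StiffnessFit:
    """Estimate the stiffness exponents from the envelope head and tail.

    ``method="height"`` (default): the head range runs from the first beat
    up to the first beat reaching ``head_fraction`` of the peak amplitude on
    the rising side; the tail range from the last beat above
    ``tail_fraction`` of the peak on the falling side to the end.  The
    default 1/3 and 2/3 heights keep both ranges inside the pure collapse /
    pure distension domains for physiological envelopes.

    ``method="inflection"``: the head ends at the beat of maximal rising
    slope and the tail starts at the beat of maximal falling slope
    (numerical slopes of amplitude vs pressure); noisier but parameter-free.

    Returns ``a_hat = -slope`` of ln(amplitude) vs pressure in the head and
    ``b_hat = +slope`` in the tail, with regression diagnostics.
    """
    P = env.pressures
    A = env.amplitudes
    finite_pos = np.isfinite(A) & (A > 0.0)
    n_dropped = int(np.count_nonzero(~finite_pos))
    if n_dropped:
        logger.info("fit_stiffness: dropped %d beats with non-positive amplitude", n_dropped)
    idx = np.nonzero(finite_pos)[0]
    if idx.size < 3:
        raise ValueError("fewer than 3 beats with positive amplitude")
    peak_rel = int(np.argmax(A[idx]))
    peak = float(A[idx[peak_rel]])

    if method == "height":
        rising = idx[: peak_rel + 1]
        reach = np.nonzero(A[rising] >= head_fraction * peak)[0]
        head = rising[: reach[0] + 1] if reach.size else rising
        falling = idx[peak_rel:]
        above = np.nonzero(A[falling] >= tail_fraction * peak)[0]
        tail = falling[above[-1] :] if above.size else falling
    elif method == "inflection":
        slopes = np.gradient(A[idx], P[idx])
        head = idx[: int(np.argmin(slopes[: peak_rel + 1])) + 1]  # dA/dP most negative = rising
        tail = idx[peak_rel + int(np.argmax(slopes[peak_rel:])) :]
    else:
        raise ValueError(f"unknown method {method!r}")

    if head.size < 3:
        raise ValueError(f"head range has only {head.size} beats; need at least 3")
    if tail.size < 3:
        raise ValueError(f"tail range has only {tail.size} beats; need at least 3")

    slope_head, log_k1 = _ols_line(P[head], np.log(A[head]))
    slope_tail, log_k3 = _ols_line(P[tail], np.log(A[tail]))
    a_hat, b_hat = -slope_head, slope_tail
    if a_hat <= 0 or b_hat <= 0:
        raise ValueError(
            f"regression produced non-positive stiffness (a_hat={a_hat:.4g}, "
            f"b_hat={b_hat:.4g}); envelope head/tail are not exponential"
        )
    logger.info(
        "fit_stiffness: a_hat=%.4f (%d beats), b_hat=%.4f (%d beats)",
        a_hat,
        head.size,
        b_hat,
        tail.size,
    )
    return StiffnessFit(
        a_hat=a_hat,
        b_hat=b_hat,
        slope_head=slope_head,
        slope_tail=slope_tail,
        log_k1=log_k1,
        log_k3=log_k3,
        n_head=int(head.size),
        n_tail=int(tail.size),
        head_indices=head,
        tail_indices=tail,
        n_dropped=n_dropped,
    )


def predicted_envelope(
    P,
    SBP_test: float,
    DBP_test: float,
    a_hat: float,
    b_hat: float,
    cuff: CuffModel | None = None,
):
    """Model-predicted oscillation amplitude at cuff pressure(s) ``P``.

    ``yhat(P) = [Va(SBP-P) - Va(DBP-P)] * (P + 760) / V0`` with unit
    zero-pressure volume; both volume constants cancel once the envelope is
    amplitude-normalised, so ``V0`` (taken from ``cuff`` if given, else 1)
    only sets an arbitrary scale.
    """
    if not SBP_test > DBP_test:
        raise ValueError(f"SBP_test={SBP_test} must exceed DBP_test={DBP_test}")
    P = np.asarray(P, dtype=float)
    V0 = cuff.V0 if cuff is not None else 1.0
    artery = ArteryModel(a=a_hat, b=b_hat, Va0=1.0)
    dva = pulse_volume(DBP_test - P, SBP_test - DBP_test, artery)
    out = dva * (P + ATM_MMHG) / V0
    return out if out.ndim else float(out)


def sum_of_squares(
    env: Envelope,
    SBP_test: float,
    DBP_test: float,
    a_hat: float,
    b_hat: float,
    cuff: CuffModel | None = None,
) -> float:
    """Normalised misfit between observed and predicted envelopes.

    ``SS = sum over beats of (y/y_max - yhat/yhat_max)^2`` with
    ``yhat_max`` taken over the same beats' pressures, keeping both
    normalisations on identical support.  A degenerate prediction
    (``yhat_max <= 0``) returns ``inf`` rather than raising, so a grid
    sweep can simply skip it as the worst possible fit.
    """
    if len(env) == 0:
        raise ValueError("empty envelope")
    ymax = env.peak_amp
    if not ymax > 0:
        raise ValueError("envelope peak amplitude must be positive")
    yhat = predicted_envelope(env.pressures, SBP_test, DBP_test, a_hat, b_hat, cuff)
    yhat_max = float(np.max(yhat))
    if not np.isfinite(yhat_max) or yhat_max <= 0.0:
        return float("inf")
    resid = env.amplitudes / ymax - yhat / yhat_max
    return float(np.sum(resid**2))


@dataclass
class EstimationResult:
    """Output of the envelope-matching grid search."""

    SBP_hat: float
    DBP_hat: float
    a_hat: float
    b_hat: float
    ss_min: float
    ss_surface: np.ndarray = field(repr=False)  # shape (len(sbp_grid), len(dbp_grid))
    sbp_grid: np.ndarray = field(repr=False)
    dbp_grid: np.ndarray = field(repr=False)
    stiffness: StiffnessFit | None = None

    def __post_init__(self) -> None:
        if not self.SBP_hat > self.DBP_hat:
            raise ValueError("estimated SBP must exceed estimated DBP")

    def to_dict(self) -> dict:
        """JSON-serialisable summary (without the full surface)."""
        d = {
            "SBP_hat": self.SBP_hat,
            "DBP_hat": self.DBP_hat,
            "a_hat": self.a_hat,
            "b_hat": self.b_hat,
            "ss_min": self.ss_min,
            "grid": {
                "sbp_min": float(self.sbp_grid[0]),
                "sbp_max": float(self.sbp_grid[-1]),
                "dbp_min": float(self.dbp_grid[0]),
                "dbp_max": float(self.dbp_grid[-1]),
            },
        }
        if self.stiffness is not None:
            s = self.stiffness
            d["regression"] = {
                "slope_head": s.slope_head,
                "slope_tail": s.slope_tail,
                "log_k1": s.log_k1,
                "log_k3": s.log_k3,
                "n_head": s.n_head,
                "n_tail": s.n_tail,
                "n_dropped": s.n_dropped,
            }
        return d


def estimate_pressures(
    env: Envelope,
    cuff: CuffModel | None = None,
    grid_step: float = 1.0,
    stiffness: StiffnessFit | None = None,
    margin: float = 10.0,
) -> EstimationResult:
    """Grid-search the (SBP, DBP) pair whose envelope best fits the data.

    Candidate diastolic pressures run from ``min(P_beat) - margin`` up to
    the envelope-peak pressure, systolic candidates from the peak pressure
    up to ``max(P_beat) + margin``, both on a ``grid_step`` lattice anchored
    at integer mmHg (default step 1 mmHg).  The estimated pair therefore
    always brackets the envelope peak.  Ties are broken deterministically
    toward the smallest pulse pressure, then the smallest SBP.

    The stiffness exponents are taken from ``stiffness`` or fitted here
    with the default head/tail height rule.
    """
    if stiffness is None:
        stiffness = fit_stiffness(env)
    a_hat, b_hat = stiffness.a_hat, stiffness.b_hat

    P = env.pressures
    P_max = env.P_max
    dbp_grid = np.arange(np.floor(P.min()) - margin, np.floor(P_max) + 0.5 * grid_step, grid_step)
    sbp_grid = np.arange(np.ceil(P_max), np.ceil(P.max()) + margin + 0.5 * grid_step, grid_step)
    if dbp_grid.size == 0 or sbp_grid.size == 0:
        raise ValueError("empty candidate grid; envelope pressure support is degenerate")

    artery_s = ArteryModel(a=a_hat, b=b_hat, Va0=1.0)
    V0 = cuff.V0 if cuff is not None else 1.0
    vol_s = artery_volume(sbp_grid[:, None] - P[None, :], artery_s)  # (nS, nB)
    vol_d = artery_volume(dbp_grid[:, None] - P[None, :], artery_s)  # (nD, nB)
    yhat = (vol_s[:, None, :] - vol_d[None, :, :]) * (P + ATM_MMHG) / V0  # (nS, nD, nB)

    feasible = sbp_grid[:, None] > dbp_grid[None, :]
    yhat_max = yhat.max(axis=2)
    y = env.amplitudes / env.peak_amp
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = y[None, None, :] - yhat / yhat_max[:, :, None]
        ss = np.einsum("ijk,ijk->ij", resid, resid)
    ss[~feasible | (yhat_max <= 0.0) | ~np.isfinite(yhat_max)] = np.inf

    ss_min = float(np.min(ss))
    if not np.isfinite(ss_min):
        raise ValueError("no feasible (SBP, DBP) candidate on the grid")
    ties = np.argwhere(ss == ss_min)
    pp = sbp_grid[ties[:, 0]] - dbp_grid[ties[:, 1]]
    order = np.lexsort((sbp_grid[ties[:, 0]], pp))
    i_s, i_d = ties[order[0]]

    logger.info(
        "grid search: %d x %d candidates, minimum SS=%.4g at %g/%g",
        sbp_grid.size,
        dbp_grid.size,
        ss_min,
        sbp_grid[i_s],
        dbp_grid[i_d],
    )
    return EstimationResult(
        SBP_hat=float(sbp_grid[i_s]),
        DBP_hat=float(dbp_grid[i_d]),
        a_hat=a_hat,
        b_hat=b_hat,
        ss_min=ss_min,
        ss_surface=ss,
        sbp_grid=sbp_grid,
        dbp_grid=dbp_grid,
        stiffness=stiffness,
    )
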