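"""Free-energy estimation from per-window samples.

The production path is deliberately simple: fixed equilibration discard and
stride subsampling, Bennett acceptance ratio (BAR) between neighbouring
lambda-states, and a plain sum over windows.  The multistate estimator
(MBAR) is available for diagnostics only: when samples from nearly
decoupled states are re-evaluated at strongly coupled states they can
acquire unphysically low energies and hence essentially all of the MBAR
weight, silently corrupting the result.  ``mbar_with_diagnostics`` flags
exactly that pathology instead of trusting the numbers.

Headline uncertainties come from repeat statistics (sample standard
deviation over independent replicas), with the per-window BAR asymptotic
error available alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .system import ThermoState

__all__ = [
    "EnergyMatrix",
    "BarResult",
    "FreeEnergyResult",
    "MbarReport",
    "subsample",
    "bar",
    "exponential_averaging",
    "sum_windows",
    "mbar_with_diagnostics",
    "repeat_statistics",
]


def subsample(n_frames: int) -> np.ndarray:
    """Retained frame indices: drop the first 20 %, then take every 4th.

    ``n_frames`` may also be a sequence of frames, in which case its length
    is used.  With 4000 saved frames this retains exactly 800.
    """
    if not np.isscalar(n_frames):
        n_frames = len(n_frames)
    n_frames = int(n_frames)
    if n_frames < 5:
        raise ValueError("need at least 5 frames to subsample")
    start = n_frames // 5
    return np.arange(start, n_frames, 4)


@dataclass(frozen=True)
class BarResult:
    """One window's BAR estimate, kcal/mol."""

    delta_g: float
    stderr: float
    low_overlap: bool = False


def _bar_residual(df, w_f, w_r, m):
    # Bennett self-consistency in reduced units: sum of Fermi terms.
    return (np.sum(expit(-(m + w_f - df)))
            - np.sum(expit(-(-m + w_r + df))))


def bar(forward_works: np.ndarray, reverse_works: np.ndarray,
        thermo: ThermoState | None = None) -> BarResult:
    """Bennett acceptance ratio between two neighbouring states.

    Parameters
    ----------
    forward_works
        Reduced works ``u_1(x) - u_0(x)`` for samples from state 0.
    reverse_works
        Reduced works ``u_0(x) - u_1(x)`` for samples from state 1.
    thermo
        Converts the reduced result to kcal/mol; if omitted the result is
        in units of k_B T.

    The self-consistent acceptance-ratio equation is solved by bisection
    to |residual| < 1e-10 (in units of samples).  If the two work
    distributions do not overlap the estimate is unreliable; a warning is
    emitted and the result flagged.
    """
    w_f = np.asarray(forward_works, dtype=float)
    w_r = np.asarray(reverse_works, dtype=float)
    if len(w_f) == 0 or len(w_r) == 0:
        raise ValueError("both work sets must be non-empty")
    n_f, n_r = len(w_f), len(w_r)
    m = np.log(n_f / n_r)

    # No overlap: every forward work far above every (negated) reverse work,
    # i.e. the two states' work distributions share no support.
    low_overlap = bool(w_f.min() - (-w_r).max() > 10.0)
    if low_overlap:
        warnings.warn("BAR: forward and reverse work distributions barely "
                      "overlap; estimate flagged", stacklevel=2)

    lo = min(w_f.min(), (-w_r).min()) - 1.0
    hi = max(w_f.max(), (-w_r).max()) + 1.0
    r_lo, r_hi = _bar_residual(lo, w_f, w_r, m), _bar_residual(hi, w_f, w_r, m)
    # The residual is monotone increasing in df; expand until bracketed.
    for _ in range(200):
        if r_lo <= 0 <= r_hi:
            break
        if r_lo > 0:
            lo -= max(1.0, hi - lo)
            r_lo = _bar_residual(lo, w_f, w_r, m)
        if r_hi < 0:
            hi += max(1.0, hi - lo)
            r_hi = _bar_residual(hi, w_f, w_r, m)
    for _ in range(20000):
        mid = 0.5 * (lo + hi)
        r_mid = _bar_residual(mid, w_f, w_r, m)
        if abs(r_mid) < 1e-10 or (hi - lo) < 1e-15 * max(1.0, abs(mid)):
            break
        if r_mid < 0:
            lo = mid
        else:
            hi = mid
    df = 0.5 * (lo + hi)

    # First-order asymptotic variance (Bennett 1976) in reduced units.
    f_f = expit(-(m + w_f - df))
    f_r = expit(-(-m + w_r + df))
    with np.errstate(divide="ignore", invalid="ignore"):
        var = ((np.mean(f_f ** 2) / np.mean(f_f) ** 2 - 1.0) / n_f
               + (np.mean(f_r ** 2) / np.mean(f_r) ** 2 - 1.0) / n_r)
    stderr = float(np.sqrt(max(var, 0.0)))

    scale = 1.0 / thermo.beta if thermo is not None else 1.0
    return BarResult(delta_g=float(df) * scale, stderr=stderr * scale,
                     low_overlap=low_overlap)


def exponential_averaging(forward_works: np.ndarray,
                          thermo: ThermoState | None = None) -> float:
    """One-sided free-energy perturbation (Zwanzig); internal baseline.

    Higher-variance than BAR on the same data; used as a comparison
    baseline, never for production estimates.
    """
    w = np.asarray(forward_works, dtype=float)
    df = -(logsumexp(-w) - np.log(len(w)))
    return float(df) * (1.0 / thermo.beta if thermo is not None else 1.0)


def sum_windows(per_window, schedule=None) -> float:
    """Total free energy as the plain sum of per-window differences.

    If ``schedule`` is given its length must be one more than the number
    of windows (contiguous coverage); a mismatch is a schedule gap.
    """
    per_window = np.asarray(per_window, dtype=float)
    if schedule is not None and len(schedule) != len(per_window) + 1:
        raise ValueError("schedule gap: need exactly one window per "
                         "adjacent lambda pair")
    return float(np.sum(per_window))


def repeat_statistics(totals):
    """Mean and sample standard deviation (n-1) over independent repeats.

    A single repeat yields (mean, nan) — the std is undefined, flagged by
    the NaN rather than a silent zero.
    """
    totals = np.asarray(totals, dtype=float)
    if len(totals) == 0:
        raise ValueError("no repeats")
    if len(totals) == 1:
        return float(totals[0]), float("nan")
    return float(np.mean(totals)), float(np.std(totals, ddof=1))


@dataclass
class EnergyMatrix:
    """Reduced energies of all samples re-evaluated at all states.

    ``u`` has shape (K, N_tot): row l holds u_l(x_n) for every retained
    sample n (samples concatenated state by state); ``counts[k]`` is the
    number of samples drawn from state k; ``lambdas`` the state labels.
    """

    u: np.ndarray
    counts: np.ndarray
    lambdas: np.ndarray = None

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.u.shape[1] != self.counts.sum():
            raise ValueError("u columns must equal total sample count")
        if np.any(self.counts <= 0):
            raise ValueError("each state needs at least one sample")

    @property
    def n_states(self) -> int:
        return self.u.shape[0]

    def state_of_sample(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_states), self.counts)

    def to_frame(self):
        """Long-format table: state sampled, sample index, state
        evaluated (lambda if known), reduced energy."""
        import pandas as pd

        state_of = self.state_of_sample()
        rows = {
            "state_sampled": np.tile(state_of, self.n_states),
            "sample": np.tile(np.arange(self.u.shape[1]), self.n_states),
            "state_evaluated": np.repeat(np.arange(self.n_states),
                                         self.u.shape[1]),
            "reduced_energy": self.u.ravel(),
        }
        df = pd.DataFrame(rows)
        if self.lambdas is not None:
            lams = np.asarray(self.lambdas, dtype=float)
            df["lambda_evaluated"] = lams[df["state_evaluated"]]
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


@dataclass
class MbarReport:
    """Outcome of an MBAR attempt with pathology diagnostics.

    ``delta_f`` is per-state reduced free energies relative to state 0, or
    None on non-convergence.  ``flagged`` lists (state_evaluated, sample)
    pairs whose re-evaluated reduced energy lies implausibly far below
    anything actually sampled at that state; ``flagged_weights`` the MBAR
    weight each flagged sample carries in that state's average.
    """

    delta_f: np.ndarray | None
    converged: bool
    flagged: list = field(default_factory=list)
    flagged_weights: list = field(default_factory=list)
    n_iterations: int = 0


def mbar_with_diagnostics(matrix: EnergyMatrix, tol: float = 1e-8,
                          max_iter: int = 2000,
                          pathology_threshold: float = 50.0) -> MbarReport:
    """Self-consistent MBAR with the low-energy-outlier diagnostic.

    Any sample whose re-evaluated reduced energy at some state lies more
    than ``pathology_threshold`` (k_B T units) below the minimum energy of
    the samples actually drawn from that state is flagged, together with
    the MBAR weight it would carry there — such samples dominate the
    estimate while representing configurations the state never visits.
    Non-convergence returns a report with ``delta_f=None`` instead of
    raising, so a BAR-based pipeline can proceed.
    """
    u = matrix.u
    counts = matrix.counts
    k_states, _ = u.shape
    log_n = np.log(counts)

    f = np.zeros(k_states)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator per sample: logsumexp_m [log N_m + f_m - u_m(x)]
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        new_f = -logsumexp(-u - log_denom[None, :], axis=1)
        new_f = new_f - new_f[0]
        if not np.all(np.isfinite(new_f)):
            break
        if np.max(np.abs(new_f - f)) < tol:
            f = new_f
            converged = True
            break
        f = new_f

    # Pathology scan: compare re-evaluations against what each state
    # actually sampled.  The reported weight is the sample's share of the
    # target state's Boltzmann weight over the pooled samples — the
    # quantity a reweighting estimator would assign it; one unphysically
    # low energy swallows essentially all of it.
    state_of = matrix.state_of_sample()
    flagged, flagged_weights = [], []
    for l in range(k_states):
        own = u[l, state_of == l]
        floor = own.min() - pathology_threshold
        bad = np.where((u[l] < floor) & (state_of != l))[0]
        if len(bad) == 0:
            continue
        log_w = -u[l] - logsumexp(-u[l])
        for n in bad:
            flagged.append((l, int(n)))
            flagged_weights.append(float(np.exp(log_w[n])))

    return MbarReport(
        delta_f=f if converged else None,
        converged=converged,
        flagged=flagged,
        flagged_weights=flagged_weights,
        n_iterations=it,
    )


@dataclass
class FreeEnergyResult:
    """A free-energy leg with per-window and per-repeat bookkeeping.

    ``window_dgs`` has shape (n_repeats, n_windows) in kcal/mol; repeat
    totals are their sums (sign convention applied by the protocol that
    produced the result).  ``value``/``stderr`` are the across-repeat mean
    and sample standard deviation — the headline numbers.
    """

    window_dgs: np.ndarray
    repeat_totals: np.ndarray
    value: float
    stderr: float
    estimator: str = "BAR"
    label: str = ""
    bar_stderrs: np.ndarray | None = None

    @classmethod
    def from_windows(cls, window_dgs, sign: float = 1.0, estimator="BAR",
                     label="", bar_stderrs=None) -> "FreeEnergyResult":
        window_dgs = np.atleast_2d(np.asarray(window_dgs, dtype=float))
        totals = sign * window_dgs.sum(axis=1)
        mean, std = repeat_statistics(totals)
        return cls(window_dgs=window_dgs, repeat_totals=totals,
                   value=mean, stderr=std, estimator=estimator, label=label,
                   bar_stderrs=bar_stderrs)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "estimator": self.estimator,
            "value_kcal_mol": self.value,
            "stderr_kcal_mol": self.stderr,
            "repeat_totals": [float(x) for x in self.repeat_totals],
            "window_dgs": self.window_dgs.tolist(),
        }

    def to_frame(self):
        """Per-window table (one row per repeat and window), kcal/mol."""
        import pandas as pd

        n_rep, n_win = self.window_dgs.shape
        df = pd.DataFrame({
            "repeat": np.repeat(np.arange(n_rep), n_win),
            "window": np.tile(np.arange(n_win), n_rep),
            "delta_g": self.window_dgs.ravel(),
        })
        if self.bar_stderrs is not None:
            df["bar_stderr"] = np.asarray(self.bar_stderrs).ravel()
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)
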