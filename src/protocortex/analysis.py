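"""Tuning measurement and map-level analysis of cortical selectivity.

Tuning is measured with all plasticity switched off: each probe stream is
presented, the network resets in between, and the per-neuron spike count per
direction (averaged over probe instances) forms a :class:`ResponseTable`.
From it:

* **Selectivity index (SI)** — circular vector average.  For direction
  selectivity (DS) the resultant of the 8 response vectors
  ``R = sum_k r_k * exp(i * theta_k)`` gives ``SI = |R| / sum_k r_k`` and the
  preferred angle ``arg(R)``; for orientation selectivity (OR) angles are
  doubled first and the preferred angle halved, so it lives in [0, 180).
  SI is 0 for a flat tuning curve and 1 for a one-hot one.
* **Preference maps** — per-neuron (preferred angle, SI) over the cortical
  sheet; neurons with no spikes to any direction are flagged non-responsive
  and excluded from averages.  Map "patchiness" is quantified by the spatial
  autocorrelation of preferred angles at a given grid lag.
* **Cumulative SI curves**, **aligned tuning curves** (each neuron's row
  rotated so its preferred direction sits at 0 deg, then sum-normalized) and
  a constrained **double-Gaussian fit** (preferred lobe fixed at 0 deg, null
  lobe at 180 deg, shared width).
* **Group comparisons** via two-sided Mann-Whitney rank-sum tests with
  Bonferroni-adjusted alpha, and counts of neurons "converted" to a target
  direction within a circular tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dynamics import LIFParams, LearningFlags, run_presentation
from .network import Network, Pathway, grid_coords
from .stimulus import COMPASS, EventStream

__all__ = [
    "ResponseTable",
    "SelectivityMap",
    "TuningFit",
    "measure_tuning",
    "selectivity_index",
    "build_preference_map",
    "cumulative_curve",
    "align_tuning",
    "fit_double_gaussian",
    "count_converted",
    "compare_groups",
    "weight_change_map",
    "angular_autocorrelation",
]

DIRECTIONS_DEG = np.array(sorted(COMPASS.values()))  # 0, 45, ..., 315


@dataclass
class ResponseTable:
    """Per-neuron mean spike count for each of the 8 probe directions."""

    counts: np.ndarray  # (n_neurons, 8), column k = DIRECTIONS_DEG[k]
    directions_deg: np.ndarray = field(
        default_factory=lambda: DIRECTIONS_DEG.copy()
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 8:
            raise ValueError("counts must be (n_neurons, 8)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def responsive(self) -> np.ndarray:
        """Neurons with at least one spike to at least one direction."""
        return self.counts.sum(axis=1) > 0

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"dir_{int(d)}": self.counts[:, k]
                for k, d in enumerate(self.directions_deg)}
        df = pd.DataFrame(cols)
        df.insert(0, "neuron", np.arange(self.n_neurons))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class SelectivityMap:
    """Preferred angle + SI per neuron on the cortical grid."""

    preferred_deg: np.ndarray
    si: np.ndarray
    responsive: np.ndarray
    mode: str  # "DS" or "OR"
    grid_shape: tuple[int, int]

    @property
    def mean_si(self) -> float:
        """Mean SI over responsive neurons."""
        if not self.responsive.any():
            return float("nan")
        return float(self.si[self.responsive].mean())

    def to_dataframe(self) -> pd.DataFrame:
        pos = grid_coords(np.arange(len(self.si)), self.grid_shape)
        return pd.DataFrame({
            "neuron": np.arange(len(self.si)),
            "x": pos[:, 0].astype(int),
            "y": pos[:, 1].astype(int),
            "preferred_deg": self.preferred_deg,
            "si": self.si,
            "responsive": self.responsive,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class TuningFit:
    """Constrained double-Gaussian fit of an aligned mean tuning curve."""

    amp_preferred: float
    amp_null: float
    sigma_deg: float
    baseline: float
    residual: float
    degenerate: bool = False


def measure_tuning(
    network: Network,
    test_set: list[EventStream],
    lif: LIFParams | None = None,
    engine: str = "auto",
) -> ResponseTable:
    """Probe all 8 directions with plasticity off; weights are untouched.

    ``test_set`` must cover every compass direction; multiple instances per
    direction are averaged.
    """
    present = {s.direction_deg for s in test_set}
    missing = set(DIRECTIONS_DEG) - present
    if missing:
        raise ValueError(
            f"test_set is missing directions {sorted(missing)} deg; all 8 "
            "compass directions are required"
        )
    flags = LearningFlags(afferent=False, lateral=False)
    counts = np.zeros((network.n_cortex, 8))
    n_inst = np.zeros(8)
    for s in test_set:
        k = int(np.nonzero(DIRECTIONS_DEG == s.direction_deg)[0][0])
        rec = run_presentation(network, s, learning=flags, lif=lif,
                               engine=engine)
        counts[:, k] += rec.cortex_counts()
        n_inst[k] += 1
    counts /= n_inst
    return ResponseTable(counts=counts)


def selectivity_index(
    responses_8dir: np.ndarray, mode: str = "DS"
) -> tuple[float, float]:
    """Vector-average preferred angle and SI for one neuron.

    Returns ``(preferred_deg, si)``.  Raises on an all-zero response row
    (such a neuron is non-responsive and must be excluded upstream).
    """
    r = np.asarray(responses_8dir, dtype=float)
    if r.shape != (8,):
        raise ValueError("expected 8 responses, one per compass direction")
    if np.any(r < 0):
        raise ValueError("responses must be non-negative")
    total = r.sum()
    if total == 0:
        raise ValueError("all-zero responses: neuron is non-responsive")
    if mode == "DS":
        mult = 1.0
    elif mode == "OR":
        mult = 2.0
    else:
        raise ValueError(f"mode must be 'DS' or 'OR', got {mode!r}")
    ang = np.deg2rad(DIRECTIONS_DEG * mult)
    resultant = np.sum(r * np.exp(1j * ang))
    # |R| <= sum(r) analytically; clip the float overshoot on one-hot rows
    si = float(min(np.abs(resultant) / total, 1.0))
    period = 360.0 / mult
    pref = float(np.rad2deg(np.angle(resultant)) / mult) % period
    if period - pref < 1e-9:  # -0.0-degree angles wrap back to 0
        pref = 0.0
    return pref, si


def build_preference_map(
    table: ResponseTable, mode: str = "DS",
    grid_shape: tuple[int, int] = (60, 60),
) -> SelectivityMap:
    """Elementwise vector-average map over the cortical sheet."""
    resp = table.responsive
    pref = np.full(table.n_neurons, np.nan)
    si = np.full(table.n_neurons, np.nan)
    idx = np.nonzero(resp)[0]
    if len(idx):
        r = table.counts[idx]
        mult = {"DS": 1.0, "OR": 2.0}[mode]
        ang = np.deg2rad(table.directions_deg * mult)
        resultant = (r * np.exp(1j * ang)).sum(axis=1)
        si[idx] = np.minimum(np.abs(resultant) / r.sum(axis=1), 1.0)
        period = 360.0 / mult
        p = (np.rad2deg(np.angle(resultant)) / mult) % period
        pref[idx] = np.where(period - p < 1e-9, 0.0, p)
    return SelectivityMap(pref, si, resp, mode, grid_shape)


def cumulative_curve(
    si_values: np.ndarray, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative percentage of SI values per bin over [0, 1].

    Returns ``(bin_upper_edges, cumulative_pct)``; the curve is monotone
    non-decreasing and ends at 100%.
    """
    si = np.asarray(si_values, dtype=float)
    if si.size == 0:
        raise ValueError("si_values must be non-empty")
    if np.any((si < 0) | (si > 1)):
        raise ValueError("SI values must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(si, bins=edges)
    # Values exactly at 1.0 fall in the last bin via np.histogram semantics.
    cum = 100.0 * np.cumsum(hist) / si.size
    return edges[1:], cum


def _circ_diff(a_deg: np.ndarray, b_deg: float, period: float = 360.0):
    """Signed minimal circular difference a - b."""
    d = (np.asarray(a_deg, dtype=float) - b_deg) % period
    return np.where(d > period / 2, d - period, d)


def align_tuning(
    table: ResponseTable,
    prev_preferred_deg: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate each responsive row so its peak sits at relative angle 0.

    Rows are normalized by their sum over the 8 directions, so relative
    angle 180 holds the null response and 90/270 the orthogonal ones.
    Ties for the maximum go to the angle closest (circularly) to
    ``prev_preferred_deg`` when given, else to the lowest angle.

    Returns ``(aligned, neuron_ids)`` where ``aligned`` is
    (n_responsive, 8) over relative angles 0, 45, ..., 315.
    """
    resp = table.responsive
    ids = np.nonzero(resp)[0]
    rows = table.counts[ids]
    norm = rows / rows.sum(axis=1, keepdims=True)

    aligned = np.empty_like(norm)
    for out_i, (nid, row) in enumerate(zip(ids, norm)):
        maxima = np.nonzero(row == row.max())[0]
        if len(maxima) > 1 and prev_preferred_deg is not None and np.isfinite(
            prev_preferred_deg[nid]
        ):
            dist = np.abs(
                _circ_diff(DIRECTIONS_DEG[maxima], prev_preferred_deg[nid])
            )
            k = maxima[np.argmin(dist)]
        else:
            k = maxima[0]
        aligned[out_i] = np.roll(row, -k)
    return aligned, ids


def _double_gaussian(theta_deg, a_p, a_n, sigma, baseline):
    dp = _circ_diff(theta_deg, 0.0)
    dn = _circ_diff(theta_deg, 180.0)
    return (
        a_p * np.exp(-(dp**2) / (2 * sigma**2))
        + a_n * np.exp(-(dn**2) / (2 * sigma**2))
        + baseline
    )


def fit_double_gaussian(aligned_mean_curve: np.ndarray) -> TuningFit:
    """Least-squares fit of two Gaussian lobes with shared width.

    The preferred lobe is fixed at 0 deg and the null lobe at 180 deg
    (circular angle distance); amplitudes are constrained non-negative.
    A flat input is reported with ``degenerate=True`` (the width is then
    unidentifiable) rather than raising.
    """
    y = np.asarray(aligned_mean_curve, dtype=float)
    if y.shape != (8,):
        raise ValueError("expected 8 aligned mean responses")
    theta = DIRECTIONS_DEG.astype(float)

    if np.ptp(y) < 1e-12:
        return TuningFit(
            amp_preferred=0.0, amp_null=0.0, sigma_deg=float("nan"),
            baseline=float(y.mean()), residual=0.0, degenerate=True,
        )

    lo = float(y.min())

    def residuals(p):
        return _double_gaussian(theta, *p) - y

    best = None
    for sigma0 in (20.0, 40.0, 70.0):
        p0 = [max(y[0] - lo, 1e-6), max(y[4] - lo, 1e-6), sigma0, lo]
        try:
            res = optimize.least_squares(
                residuals, p0,
                bounds=([0, 0, 1.0, -np.inf], [np.inf, np.inf, 360.0, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("double-Gaussian fit failed to converge")
    a_p, a_n, sigma, b = best.x
    return TuningFit(
        amp_preferred=float(a_p), amp_null=float(a_n),
        sigma_deg=float(sigma), baseline=float(b),
        residual=float(np.sqrt(2 * best.cost)),
    )


def count_converted(
    map_before: SelectivityMap,
    map_after: SelectivityMap,
    direction_deg: float,
    tol_deg: float = 5.0,
) -> int:
    """Responsive neurons whose trained preference lies within a tolerance.

    Counts neurons of ``map_after`` whose preferred angle is within
    ``tol_deg`` (circular distance) of ``direction_deg``.  ``map_before``
    anchors the comparison to the same population (the maps must cover the
    same neurons).
    """
    if len(map_before.si) != len(map_after.si):
        raise ValueError("maps must cover the same neurons")
    period = 360.0 if map_after.mode == "DS" else 180.0
    ok = map_after.responsive & np.isfinite(map_after.preferred_deg)
    d = np.abs(
        _circ_diff(map_after.preferred_deg[ok], direction_deg, period)
    )
    return int((d <= tol_deg).sum())


@dataclass
class GroupComparison:
    """Mann-Whitney rank-sum report with Bonferroni-adjusted alpha."""

    u_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    alpha: float
    adjusted_alpha: float
    significant: bool


def compare_groups(
    si_group_a: np.ndarray,
    si_group_b: np.ndarray,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> GroupComparison:
    """Two-sided Mann-Whitney test between two SI samples."""
    a = np.asarray(si_group_a, dtype=float)
    b = np.asarray(si_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    adj = alpha / n_comparisons
    return GroupComparison(
        u_statistic=float(u), p_value=float(p),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=a.size, n_b=b.size,
        alpha=alpha, adjusted_alpha=adj, significant=bool(p < adj),
    )


def weight_change_map(
    network_before: Network,
    network_after: Network,
    neuron_id: int,
    pathway: str,
) -> np.ndarray:
    """(final - initial) weights onto one neuron, on the source layer's grid.

    Returns a 2D array indexed ``[y, x]`` over the source grid (LGN for the
    afferent pathway, cortex for lateral ones) with NaN where the neuron has
    no synapse from that position; co-located synapses sum.
    """
    if pathway not in (Pathway.AFFERENT, Pathway.LATERAL_EXC,
                       Pathway.LATERAL_INH):
        raise ValueError(f"unknown pathway {pathway!r}")
    g0 = network_before.pathways[pathway]
    g1 = network_after.pathways[pathway]
    if len(g0) != len(g1) or not (
        np.array_equal(g0.pre, g1.pre) and np.array_equal(g0.post, g1.post)
    ):
        raise ValueError("networks have different topology on this pathway")
    cfg = network_after.config
    shape = cfg.lgn_shape if pathway == Pathway.AFFERENT else cfg.cortex_shape
    sel = g1.post == neuron_id
    delta = g1.weight[sel] - g0.weight[sel]
    pos = grid_coords(g1.pre[sel], shape).astype(int)
    grid = np.full((shape[1], shape[0]), np.nan)
    grid[pos[:, 1], pos[:, 0]] = 0.0  # zero base so co-located synapses sum
    np.add.at(grid, (pos[:, 1], pos[:, 0]), delta)
    return grid


def angular_autocorrelation(
    smap: SelectivityMap, lag: int
) -> float:
    """Mean cosine similarity of preferred angles at a given grid lag.

    Pairs are taken along the two grid axes at offset ``lag``; the angle
    difference is doubled first in OR mode.  Values near 1 indicate smooth
    local map structure ("patchiness" domains), values near 0 a salt-and-
    pepper map.
    """
    w, h = smap.grid_shape
    mult = 1.0 if smap.mode == "DS" else 2.0
    ang = np.deg2rad(smap.preferred_deg * mult).reshape(h, w)
    ok = (smap.responsive & np.isfinite(smap.preferred_deg)).reshape(h, w)
    sims = []
    for da, db in ((0, lag), (lag, 0)):
        a = ang[: h - da or None, : w - db or None]
        b = ang[da:, db:]
        m = ok[: h - da or None, : w - db or None] & ok[da:, db:]
        if m.any():
            sims.append(np.cos(a[m] - b[m]))
    if not sims:
        return float("nan")
    return float(np.concatenate(sims).mean())
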