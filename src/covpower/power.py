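"""Detection-power curve: empirical fit of power(s) and alignment summaries.

power(s) is the expected sensitivity for detecting significant covariation at
a basepair with s total substitutions, fitted from binned (s, E-value) data.
The default fit is isotonic regression (monotone by construction); a
degree-10 least-squares polynomial and a 1 - exp(-lambda s) single-parameter
curve are available as alternatives.  Above ``clamp_hi`` (default 226) power
is clamped to 1; power(0) = 0 always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.isotonic import IsotonicRegression

from .covariation import CovariationResult
from .errors import PowerError
from .msa_io import SecondaryStructure

DEFAULT_CLAMP_HI = 226.0
FIT_SPLIT_S = 150  # bins above this must show >= MIN_HIGH_POWER to be fitted
MIN_HIGH_POWER = 0.8
POLY_DEGREE = 10


@dataclass
class PowerCurve:
    """Fitted power(s) mapping stored as (s, power) knots."""

    knots_s: np.ndarray
    knots_p: np.ndarray
    fit_mode: str = "isotonic"
    clamp_hi: float = DEFAULT_CLAMP_HI

    def __post_init__(self) -> None:
        self.knots_s = np.asarray(self.knots_s, dtype=float)
        self.knots_p = np.clip(np.asarray(self.knots_p, dtype=float), 0.0, 1.0)
        if self.knots_s.size != self.knots_p.size or self.knots_s.size < 2:
            raise PowerError("curve needs >= 2 (s, power) knots")
        if (np.diff(self.knots_s) <= 0).any():
            raise PowerError("knot s values must be strictly increasing")

    @property
    def domain_lo(self) -> float:
        return float(self.knots_s[0])


@dataclass
class PowerReport:
    """Per-alignment power summary over the proposed basepair set."""

    per_bp: list[tuple[tuple[int, int], float, float, float, bool]]
    B: int
    cov_bp_exp: float
    alignment_power: float
    observed: int


def bin_pairs(
    pairs: list[tuple[float, float]], threshold: float = 0.05
) -> list[tuple[int, float, int]]:
    """Bin (s, E-value) points by integer s; per bin, report the fraction of
    points significant at E < threshold.  Empty bins are omitted."""
    if not pairs:
        raise PowerError("no (s, evalue) pairs to bin")
    totals: dict[int, int] = {}
    hits: dict[int, int] = {}
    for s, ev in pairs:
        b = int(round(s))
        totals[b] = totals.get(b, 0) + 1
        if ev < threshold:
            hits[b] = hits.get(b, 0) + 1
    return [(b, hits.get(b, 0) / totals[b], totals[b]) for b in sorted(totals)]


def bin_equal_size(
    pairs: list[tuple[float, float]], n_bins: int = 70, threshold: float = 0.05
) -> list[tuple[float, float, int]]:
    """Equal-occupancy binning by increasing s (plotting convention only):
    returns (mean s, fraction significant, n) per bin."""
    if not pairs:
        raise PowerError("no (s, evalue) pairs to bin")
    arr = sorted(pairs)
    n_bins = min(n_bins, len(arr))
    out = []
    for chunk in np.array_split(np.asarray(arr, dtype=float), n_bins):
        if chunk.size == 0:
            continue
        s_mean = float(chunk[:, 0].mean())
        frac = float((chunk[:, 1] < threshold).mean())
        out.append((s_mean, frac, len(chunk)))
    return out


def _filter_bins(binned: list[tuple[int, float, int]]) -> list[tuple[int, float, int]]:
    """Keep all bins with s <= 150; above that only bins with >= 80% power
    (sparse high-s bins are noisy and often reflect alignment problems)."""
    return [
        (s, f, n)
        for s, f, n in binned
        if s <= FIT_SPLIT_S or f >= MIN_HIGH_POWER
    ]


def fit_power_curve(
    binned: list[tuple[int, float, int]],
    fit_mode: str = "isotonic",
    clamp_hi: float = DEFAULT_CLAMP_HI,
) -> PowerCurve:
    """Fit power(s) to integer-s bins of (s, fraction_significant, n)."""
    usable = _filter_bins(binned)
    if len(usable) < 5:
        raise PowerError(f"only {len(usable)} usable bins after filtering; need >= 5")
    s = np.array([b[0] for b in usable], dtype=float)
    f = np.array([b[1] for b in usable], dtype=float)
    w = np.array([b[2] for b in usable], dtype=float)
    anchor_w = max(w.sum(), 1.0)  # force through power(0) = 0
    s_fit = np.concatenate([[0.0], s])
    f_fit = np.concatenate([[0.0], f])
    w_fit = np.concatenate([[anchor_w], w])

    grid = np.unique(np.concatenate([s_fit, np.arange(0.0, s.max() + 1.0)]))
    if fit_mode == "isotonic":
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True,
                                 out_of_bounds="clip")
        iso.fit(s_fit, f_fit, sample_weight=w_fit)
        p = iso.predict(grid)
    elif fit_mode == "polynomial":
        deg = min(POLY_DEGREE, len(s_fit) - 1)
        coeffs = np.polyfit(s_fit, f_fit, deg=deg, w=np.sqrt(w_fit))
        p = np.clip(np.polyval(coeffs, grid), 0.0, 1.0)
    elif fit_mode == "exponential":
        def model(x, lam):
            return 1.0 - np.exp(-lam * x)

        (lam,), _ = curve_fit(model, s_fit, f_fit, p0=[0.02],
                              sigma=1.0 / np.sqrt(w_fit), bounds=(1e-9, np.inf))
        p = np.clip(model(grid, lam), 0.0, 1.0)
    else:
        raise PowerError(f"unknown fit_mode {fit_mode!r}")
    p[grid == 0.0] = 0.0
    saturated = grid[p >= 1.0]
    eff_clamp = float(saturated.min()) if saturated.size else float(clamp_hi)
    eff_clamp = min(eff_clamp, clamp_hi)
    return PowerCurve(knots_s=grid, knots_p=p, fit_mode=fit_mode, clamp_hi=eff_clamp)


def power_of(curve: PowerCurve, s: float) -> float:
    """Evaluate the fitted curve at (possibly fractional) s."""
    if s < 0:
        raise PowerError(f"substitution count must be >= 0, got {s}")
    if s == 0:
        return 0.0
    if s > curve.clamp_hi:
        return 1.0
    ks, kp = curve.knots_s, curve.knots_p
    if s >= ks[-1]:
        # interpolate toward the clamp point to stay continuous and monotone
        if curve.clamp_hi > ks[-1]:
            frac = (s - ks[-1]) / (curve.clamp_hi - ks[-1])
            return float(kp[-1] + frac * (1.0 - kp[-1]))
        return 1.0
    return float(np.interp(s, ks, kp))


def power_report(
    structure: SecondaryStructure,
    curve: PowerCurve,
    cov_results: list[CovariationResult],
    evalue_threshold: float = 0.05,
) -> PowerReport:
    """Aggregate per-basepair power into cov-bp-exp and alignment power.

    ``cov_results`` should come from a two-set run so that basepair E-values
    carry the basepair-set correction.
    """
    if structure.B == 0:
        raise PowerError("alignment power is undefined for an empty structure")
    by_pair = {r.pair: r for r in cov_results}
    per_bp = []
    cov_bp_exp = 0.0
    observed = 0
    for pair in structure.pairs:
        r = by_pair.get(pair)
        if r is None:
            raise PowerError(f"no covariation result for structure pair {pair}")
        s_b = float(r.substitutions)
        p_b = power_of(curve, s_b)
        sig = r.evalue < evalue_threshold
        per_bp.append((pair, s_b, p_b, r.evalue, sig))
        r.power = p_b
        cov_bp_exp += p_b
        observed += int(sig)
    return PowerReport(
        per_bp=per_bp,
        B=structure.B,
        cov_bp_exp=cov_bp_exp,
        alignment_power=cov_bp_exp / structure.B,
        observed=observed,
    )


def classify_alignment(report: PowerReport, power_threshold: float = 0.10) -> str:
    """'high_power' iff alignment power strictly exceeds the threshold."""
    return "high_power" if report.alignment_power > power_threshold else "low_power"


# ---------------------------------------------------------------------------
# Curve file I/O: two whitespace-delimited columns (s, power) + '#' header
# ---------------------------------------------------------------------------


def write_curve(curve: PowerCurve, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# power curve fit_mode={curve.fit_mode} clamp_hi={curve.clamp_hi:g}\n"
        )
        fh.write("# s\tpower\n")
        for s, p in zip(curve.knots_s, curve.knots_p):
            fh.write(f"{s:g}\t{p:.6f}\n")


def read_curve(path: str) -> PowerCurve:
    fit_mode = "isotonic"
    clamp_hi = DEFAULT_CLAMP_HI
    ss, pp = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("fit_mode="):
                        fit_mode = tok.split("=", 1)[1]
                    elif tok.startswith("clamp_hi="):
                        clamp_hi = float(tok.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) < 2:
                raise PowerError(f"{path}: malformed curve line {line!r}")
            ss.append(float(parts[0]))
            pp.append(float(parts[1]))
    if len(ss) < 2:
        raise PowerError(f"{path}: curve file needs >= 2 knots")
    return PowerCurve(knots_s=np.array(ss), knots_p=np.array(pp),
                      fit_mode=fit_mode, clamp_hi=clamp_hi)
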