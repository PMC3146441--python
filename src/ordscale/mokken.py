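"""Nonparametric IRT checks for the raw total score.

Scalability is Loevinger's H: observed inter-item covariance relative to
the maximum attainable under the items' fixed marginals (the comonotone
rearrangement).  Monotone homogeneity is probed through restscore groups:
the m item step response functions (ISRFs) P(X_i >= k | restscore group)
must be nondecreasing across ordered groups, and under double monotonicity
ISRFs of different items may not intersect.  Violations are summarised per
item with a composite ``crit`` diagnostic read against the conventional
40 / 80 decision bands (below 40: sampling noise; above 80: doubt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ItemResponseMatrix

__all__ = [
    "loevinger_h",
    "check_monotonicity",
    "check_double_monotonicity",
    "restscore_traces",
    "severity_ordering",
    "mokken_report",
    "ScalabilityResult",
    "MonotonicityReport",
    "RestscoreTrace",
    "MokkenReport",
]

MINVI_DEFAULT = 0.03
CRIT_BANDS = (40.0, 80.0)


# ---------------------------------------------------------------------------
# Loevinger's H
# ---------------------------------------------------------------------------

def _max_cross_moment(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Max of sum(x*y) over couplings of two categorical margins (comonotone)."""
    total = 0.0
    a, b = len(counts_a) - 1, len(counts_b) - 1
    ra, rb = float(counts_a[a]), float(counts_b[b])
    while a >= 0 and b >= 0:
        take = min(ra, rb)
        total += take * a * b
        ra -= take
        rb -= take
        if ra <= 0:
            a -= 1
            if a >= 0:
                ra = float(counts_a[a])
        if rb <= 0:
            b -= 1
            if b >= 0:
                rb = float(counts_b[b])
    return total


@dataclass(frozen=True)
class ScalabilityResult:
    """Loevinger's H at pair, item and scale level."""

    H: float
    H_se: float
    item_H: pd.Series
    pair_H: pd.DataFrame
    excluded_items: tuple = ()


def loevinger_h(
    matrix: ItemResponseMatrix, se: bool = True, n_categories: int = 4
) -> ScalabilityResult:
    """Scalability coefficients H_ij, H_j and scale H.

    H_ij divides the observed covariance of an item pair by the maximum
    covariance attainable given both marginals; item and scale coefficients
    aggregate numerators and denominators over pairs.  Constant items are
    excluded with a warning and named in the result.  The scale-level
    standard error is a respondent jackknife.
    """
    vals = matrix.values
    labels = list(matrix.item_labels)
    keep = [j for j in range(vals.shape[1]) if np.unique(vals[:, j]).size > 1]
    excluded = tuple(labels[j] for j in range(vals.shape[1]) if j not in keep)
    if excluded:
        import logging

        logging.getLogger(__name__).warning("constant items excluded from H: %s", excluded)
    if len(keep) < 2:
        raise ValueError("need at least two non-constant items")
    vals = vals[:, keep]
    labels = [labels[j] for j in keep]
    n, J = vals.shape

    sx = vals.sum(axis=0).astype(float)
    counts = np.stack([np.bincount(vals[:, j], minlength=n_categories) for j in range(J)])
    num = np.zeros((J, J))
    den = np.zeros((J, J))
    for i in range(J):
        for j in range(i + 1, J):
            sxy = float(vals[:, i] @ vals[:, j])
            smax = _max_cross_moment(counts[i], counts[j])
            num[i, j] = num[j, i] = n * sxy - sx[i] * sx[j]
            den[i, j] = den[j, i] = n * smax - sx[i] * sx[j]

    with np.errstate(divide="ignore", invalid="ignore"):
        pair_H = np.where(den != 0, num / den, np.nan)
    np.fill_diagonal(pair_H, np.nan)
    item_H = num.sum(axis=1) / den.sum(axis=1)
    H = float(np.sum(num) / np.sum(den))
    H_se = _jackknife_se(vals, counts, sx, n) if se else np.nan

    return ScalabilityResult(
        H=H,
        H_se=H_se,
        item_H=pd.Series(item_H, index=labels, name="H_j"),
        pair_H=pd.DataFrame(pair_H, index=labels, columns=labels),
        excluded_items=excluded,
    )


def _jackknife_se(vals, counts, sx, n):
    """Leave-one-respondent-out jackknife SE for the scale H.

    Only 16 distinct removals exist per pair (one per response-pair cell),
    so numerator/denominator deltas are tabulated per cell and gathered.
    """
    J = vals.shape[1]
    cats = counts.shape[1]
    num_lookup = {}
    den_lookup = {}
    m = n - 1
    for i in range(J):
        for j in range(i + 1, J):
            sxy = float(vals[:, i] @ vals[:, j])
            joint = np.bincount(cats * vals[:, i] + vals[:, j], minlength=cats * cats)
            joint = joint.reshape(cats, cats)
            ntab = np.zeros((cats, cats))
            dtab = np.ones((cats, cats))
            for a in range(cats):
                ci = counts[i].astype(float)
                ci[a] -= 1
                for b in range(cats):
                    if joint[a, b] == 0:
                        continue
                    cj = counts[j].astype(float)
                    cj[b] -= 1
                    smax = _max_cross_moment(ci, cj)
                    sx_i, sx_j = sx[i] - a, sx[j] - b
                    ntab[a, b] = m * (sxy - a * b) - sx_i * sx_j
                    dtab[a, b] = m * smax - sx_i * sx_j
            num_lookup[(i, j)] = ntab
            den_lookup[(i, j)] = dtab
    num_r = np.zeros(n)
    den_r = np.zeros(n)
    for i in range(J):
        for j in range(i + 1, J):
            a = vals[:, i]
            b = vals[:, j]
            num_r += num_lookup[(i, j)][a, b]
            den_r += den_lookup[(i, j)][a, b]
    h_loo = num_r / den_r
    return float(np.sqrt((n - 1) / n * np.sum((h_loo - h_loo.mean()) ** 2)))


# ---------------------------------------------------------------------------
# Restscore grouping
# ---------------------------------------------------------------------------

def default_minsize(n: int) -> int:
    """MSP-style default: n/10 (floor 50) for large samples, n/5 otherwise."""
    if n >= 500:
        return max(int(round(n / 10)), 50)
    return max(int(round(n / 5)), 10)


def _restscore_groups(rest: np.ndarray, minsize: int):
    """Partition sorted restscores into contiguous groups of >= minsize."""
    values, counts = np.unique(rest, return_counts=True)
    groups = []
    current, size = [], 0
    for v, c in zip(values, counts):
        current.append(v)
        size += c
        if size >= minsize:
            groups.append((current[0], current[-1]))
            current, size = [], 0
    if current:
        if groups:
            lo, _ = groups.pop()
            groups.append((lo, current[-1]))
        else:
            groups.append((current[0], current[-1]))
    if len(groups) < 2:
        raise ValueError("too few distinct restscores to form two groups")
    edges = np.array([hi for _, hi in groups[:-1]])
    membership = np.searchsorted(edges, rest, side="left")
    return groups, membership


# ---------------------------------------------------------------------------
# Crit composite
# ---------------------------------------------------------------------------

def _crit(h_j, n_vi, n_active, max_vi, sum_vi, max_z, sum_z):
    """Composite diagnostic in the MSP tradition.

    Weighted sum of: scalability deficit (0.3 - H_j), violation count, the
    violated fraction of active comparisons, maximum and sum of violation
    magnitudes, and maximum and sum of z statistics.  Zero when no
    violations occurred.  Components are returned alongside so the
    composite can be recalibrated.
    """
    components = {
        "deficit": max(0.0, 0.3 - h_j),
        "n_violations": float(n_vi),
        "prop_violated": n_vi / n_active if n_active else 0.0,
        "max_violation": max_vi,
        "sum_violation": sum_vi,
        "max_z": max_z,
        "sum_z": sum_z,
    }
    if n_vi == 0:
        return 0.0, components
    crit = (
        50.0 * components["deficit"]
        + np.sqrt(components["n_violations"])
        + 100.0 * components["prop_violated"]
        + 100.0 * components["max_violation"]
        + 10.0 * np.sqrt(components["sum_violation"])
        + 5.0 * components["max_z"]
        + 10.0 * np.sqrt(max(components["sum_z"], 0.0))
    )
    return float(crit), components


@dataclass(frozen=True)
class ItemCheck:
    item: str
    n_violations: int
    n_active: int
    max_violation: float
    sum_violation: float
    max_z: float
    sum_z: float
    crit: float
    components: dict = field(repr=False, default_factory=dict)

    @property
    def violation_fraction(self) -> float:
        return self.n_violations / self.n_active if self.n_active else 0.0

    @property
    def band(self) -> str:
        if self.crit < CRIT_BANDS[0]:
            return "acceptable"
        if self.crit <= CRIT_BANDS[1]:
            return "inspect"
        return "doubtful"


@dataclass(frozen=True)
class MonotonicityReport:
    kind: str  # "monotonicity" or "double_monotonicity"
    items: tuple  # of ItemCheck
    minsize: int
    minvi: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "item": c.item,
                    "n_violations": c.n_violations,
                    "violation_fraction": c.violation_fraction,
                    "n_active": c.n_active,
                    "max_violation": c.max_violation,
                    "max_z": c.max_z,
                    "crit": c.crit,
                    "band": c.band,
                }
                for c in self.items
            ]
        )

    @property
    def total_violations(self) -> int:
        return sum(c.n_violations for c in self.items)

    @property
    def total_active(self) -> int:
        return sum(c.n_active for c in self.items)


def check_monotonicity(
    matrix: ItemResponseMatrix,
    minsize: int | None = None,
    minvi: float = MINVI_DEFAULT,
) -> MonotonicityReport:
    """Manifest-monotonicity check of every item against its restscore.

    For each item, respondents are grouped by restscore (total minus the
    item); each of the m=3 ISRFs is compared across every ordered pair of
    groups, and a decrease beyond ``minvi`` counts as a violation with a
    two-proportion z statistic.
    """
    n, J = matrix.n, matrix.n_items
    if minsize is None:
        minsize = default_minsize(n)
    if minsize < 10:
        raise ValueError("minsize must be at least 10")
    totals = matrix.totals()
    vals = matrix.values
    h_items = loevinger_h(matrix, se=False).item_H
    checks = []
    for j in range(J):
        rest = totals - vals[:, j]
        groups, member = _restscore_groups(rest, minsize)
        G = len(groups)
        sizes = np.bincount(member, minlength=G).astype(float)
        # isrf[k-1, g] = P(X_j >= k | group g)
        isrf = np.stack(
            [np.bincount(member[vals[:, j] >= k], minlength=G) / sizes for k in (1, 2, 3)]
        )
        n_vi, n_active = 0, 0
        max_vi = sum_vi = max_z = sum_z = 0.0
        for k in range(3):
            for g in range(G):
                for g2 in range(g + 1, G):
                    n_active += 1
                    diff = isrf[k, g] - isrf[k, g2]
                    if diff > minvi:
                        n_vi += 1
                        pooled = (
                            isrf[k, g] * sizes[g] + isrf[k, g2] * sizes[g2]
                        ) / (sizes[g] + sizes[g2])
                        se = np.sqrt(
                            max(pooled * (1 - pooled), 1e-12)
                            * (1 / sizes[g] + 1 / sizes[g2])
                        )
                        z = diff / se
                        max_vi = max(max_vi, diff)
                        sum_vi += diff
                        max_z = max(max_z, z)
                        sum_z += z
        crit, comp = _crit(h_items.iloc[j], n_vi, n_active, max_vi, sum_vi, max_z, sum_z)
        checks.append(
            ItemCheck(matrix.item_labels[j], n_vi, n_active, max_vi, sum_vi,
                      max_z, sum_z, crit, comp)
        )
    return MonotonicityReport("monotonicity", tuple(checks), minsize, minvi)


def check_double_monotonicity(
    matrix: ItemResponseMatrix,
    minsize: int | None = None,
    minvi: float = MINVI_DEFAULT,
) -> MonotonicityReport:
    """Between-item ISRF nonintersection check (double monotonicity).

    For each item pair, ISRF estimates are formed on restscore groups that
    exclude both items.  An intersection violation is a pair of groups where
    the sign of p_i(step k) - p_j(step l) reverses, with both differences
    exceeding ``minvi``; it is attributed to both items.  The z statistic is
    the weaker of the two McNemar-style discordant-count statistics (both
    sides must reverse for a genuine crossing).
    """
    n, J = matrix.n, matrix.n_items
    if minsize is None:
        minsize = default_minsize(n)
    if minsize < 10:
        raise ValueError("minsize must be at least 10")
    totals = matrix.totals()
    vals = matrix.values
    ge = np.stack([(vals >= k) for k in (1, 2, 3)])  # (3, n, J)

    agg = {
        j: {"n_vi": 0, "n_active": 0, "max_vi": 0.0, "sum_vi": 0.0,
            "max_z": 0.0, "sum_z": 0.0}
        for j in range(J)
    }

    def mcnemar_z(in_g, i, k, j, ell):
        a = int(np.sum(ge[k, in_g, i] & ~ge[ell, in_g, j]))
        b = int(np.sum(~ge[k, in_g, i] & ge[ell, in_g, j]))
        return abs(a - b) / np.sqrt(a + b) if a + b > 0 else 0.0

    for i in range(J):
        for j in range(i + 1, J):
            rest = totals - vals[:, i] - vals[:, j]
            groups, member = _restscore_groups(rest, minsize)
            G = len(groups)
            sizes = np.bincount(member, minlength=G).astype(float)
            p_i = np.stack(
                [np.bincount(member[ge[k, :, i]], minlength=G) / sizes for k in range(3)]
            )
            p_j = np.stack(
                [np.bincount(member[ge[k, :, j]], minlength=G) / sizes for k in range(3)]
            )
            for k in range(3):
                for ell in range(3):
                    d = p_i[k] - p_j[ell]  # per group
                    for g in range(G):
                        for g2 in range(g + 1, G):
                            agg[i]["n_active"] += 1
                            agg[j]["n_active"] += 1
                            if d[g] > minvi and d[g2] < -minvi:
                                mag = min(d[g], -d[g2])
                            elif d[g] < -minvi and d[g2] > minvi:
                                mag = min(-d[g], d[g2])
                            else:
                                continue
                            z = min(
                                mcnemar_z(member == g, i, k, j, ell),
                                mcnemar_z(member == g2, i, k, j, ell),
                            )
                            for item in (i, j):
                                agg[item]["n_vi"] += 1
                                agg[item]["max_vi"] = max(agg[item]["max_vi"], mag)
                                agg[item]["sum_vi"] += mag
                                agg[item]["max_z"] = max(agg[item]["max_z"], z)
                                agg[item]["sum_z"] += z

    h_items = loevinger_h(matrix, se=False).item_H
    checks = []
    for j in range(J):
        a = agg[j]
        crit, comp = _crit(h_items.iloc[j], a["n_vi"], a["n_active"], a["max_vi"],
                           a["sum_vi"], a["max_z"], a["sum_z"])
        checks.append(
            ItemCheck(matrix.item_labels[j], a["n_vi"], a["n_active"], a["max_vi"],
                      a["sum_vi"], a["max_z"], a["sum_z"], crit, comp)
        )
    return MonotonicityReport("double_monotonicity", tuple(checks), minsize, minvi)


# ---------------------------------------------------------------------------
# Restscore traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestscoreTrace:
    """Item trace estimates across restscore groups, for tables and plots."""

    table: pd.DataFrame  # item, group, rest_lo, rest_hi, size, mean, isrf1..3
    minsize: int

    def item_means(self, item) -> np.ndarray:
        sub = self.table[self.table["item"] == item].sort_values("group")
        return sub["mean"].to_numpy()


def restscore_traces(matrix: ItemResponseMatrix, minsize: int | None = None) -> RestscoreTrace:
    """Mean item score and ISRF estimates per restscore group, per item."""
    n = matrix.n
    if minsize is None:
        minsize = default_minsize(n)
    if minsize < 10:
        raise ValueError("minsize must be at least 10")
    totals = matrix.totals()
    vals = matrix.values
    rows = []
    for j, item in enumerate(matrix.item_labels):
        rest = totals - vals[:, j]
        groups, member = _restscore_groups(rest, minsize)
        sizes = np.bincount(member, minlength=len(groups)).astype(float)
        for g, (lo, hi) in enumerate(groups):
            in_g = member == g
            row = {
                "item": item,
                "group": g,
                "rest_lo": int(lo),
                "rest_hi": int(hi),
                "size": int(sizes[g]),
                "mean": float(vals[in_g, j].mean()),
            }
            for k in (1, 2, 3):
                row[f"isrf{k}"] = float(np.mean(vals[in_g, j] >= k))
            rows.append(row)
    return RestscoreTrace(table=pd.DataFrame(rows), minsize=minsize)


# ---------------------------------------------------------------------------
# Severity ordering
# ---------------------------------------------------------------------------

def severity_ordering(thresholds, loadings=None, item_labels=None) -> pd.DataFrame:
    """Order items by mean threshold location on the latent-trait metric.

    With ``loadings`` (e.g. general-factor loadings) the thresholds are
    converted to IRT difficulty parameters b = tau / lambda before
    averaging, which places all items on a common trait metric.  Ties keep
    input order (stable sort).
    """
    tau = np.atleast_2d(np.asarray(thresholds, dtype=float))
    J = tau.shape[0]
    labels = list(item_labels) if item_labels is not None else [f"i{j+1}" for j in range(J)]
    if loadings is not None:
        lam = np.asarray(loadings, dtype=float).reshape(-1)
        key = tau.mean(axis=1) / lam
    else:
        key = tau.mean(axis=1)
    order = np.argsort(key, kind="stable")
    return pd.DataFrame(
        {
            "item": [labels[j] for j in order],
            "mean_location": key[order],
        }
    )


@dataclass(frozen=True)
class MokkenReport:
    """Bundle of scalability, monotonicity and nonintersection results."""

    scalability: ScalabilityResult
    monotonicity: MonotonicityReport
    double_monotonicity: MonotonicityReport
    traces: RestscoreTrace

    def to_frame(self) -> pd.DataFrame:
        mono = {c.item: c for c in self.monotonicity.items}
        dbl = {c.item: c for c in self.double_monotonicity.items}
        rows = []
        for item in self.scalability.item_H.index:
            m, d = mono[item], dbl[item]
            rows.append(
                {
                    "item": item,
                    "H": self.scalability.item_H[item],
                    "mono_violations": m.n_violations,
                    "mono_fraction": m.violation_fraction,
                    "mono_crit": m.crit,
                    "dm_violations": d.n_violations,
                    "dm_fraction": d.violation_fraction,
                    "dm_crit": d.crit,
                }
            )
        rows.append(
            {
                "item": "scale",
                "H": self.scalability.H,
                "mono_violations": self.monotonicity.total_violations,
                "mono_fraction": (
                    self.monotonicity.total_violations / self.monotonicity.total_active
                    if self.monotonicity.total_active
                    else 0.0
                ),
                "mono_crit": np.nan,
                "dm_violations": self.double_monotonicity.total_violations,
                "dm_fraction": (
                    self.double_monotonicity.total_violations
                    / self.double_monotonicity.total_active
                    if self.double_monotonicity.total_active
                    else 0.0
                ),
                "dm_crit": np.nan,
            }
        )
        return pd.DataFrame(rows)


def mokken_report(matrix: ItemResponseMatrix, minsize: int | None = None,
                  minvi: float = MINVI_DEFAULT) -> MokkenReport:
    """Run all nonparametric checks and bundle them."""
    return MokkenReport(
        scalability=loevinger_h(matrix),
        monotonicity=check_monotonicity(matrix, minsize=minsize, minvi=minvi),
        double_monotonicity=check_double_monotonicity(matrix, minsize=minsize, minvi=minvi),
        traces=restscore_traces(matrix, minsize=minsize),
    )
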