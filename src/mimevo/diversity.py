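"""Regional predictors of aposematic-pattern richness.

Each zoogeographic region contributes one record: its tribe count (a proxy
for phylogenetic diversity), described-species count (alpha diversity),
number of distinct colour patterns, and an optional coarse abundance class.
Ordinary least squares of pattern count on tribe count or species count,
summarised by R², asks whether pattern richness tracks phylogenetic or
alpha diversity. A sensitivity helper substitutes one region's species
count (e.g. replacing a described-species figure with an estimate of the
real fauna) and reports how R² responds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionalRecord",
    "RegressionResult",
    "AbundanceCall",
    "abundance_class",
    "regress",
    "sensitivity_substitute",
    "read_regional_table",
    "write_regional_table",
    "plot_regional_panels",
]

ABUNDANCE_CLASSES = ("low", "medium", "high")

# species-per-site ranges stated alongside the individuals/month thresholds;
# advisory only (reported, never classifying)
_SPECIES_RANGES = {"low": (1, 5), "medium": (6, 30), "high": (31, 100)}


@dataclass(frozen=True)
class RegionalRecord:
    """One region's diversity summary."""

    region: str
    n_tribes: int
    n_species: int
    n_patterns: int
    abundance_class: Optional[str] = None

    def __post_init__(self):
        for name in ("n_tribes", "n_species", "n_patterns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.abundance_class is not None and (
            self.abundance_class not in ABUNDANCE_CLASSES
        ):
            raise ValueError(f"unknown abundance class {self.abundance_class!r}")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self):
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")
        if self.n < 2:
            raise ValueError("regression needs n >= 2")


@dataclass(frozen=True)
class AbundanceCall:
    """Abundance class plus whether the species count fits the class range."""

    abundance: str
    species_consistent: bool


def abundance_class(individuals_per_month: int, species_at_site: int) -> AbundanceCall:
    """Three-level abundance classification.

    The individuals/month thresholds classify (<100 low, 100–300 medium,
    >300 high; the boundary values 100 and 300 are medium by the interval
    notation). The species-at-site count is advisory: it is checked against
    the class's stated range and reported as consistent or not, but never
    overrides the classification.
    """
    if individuals_per_month < 0 or species_at_site < 0:
        raise ValueError("inputs must be non-negative")
    if individuals_per_month < 100:
        cls = "low"
    elif individuals_per_month <= 300:
        cls = "medium"
    else:
        cls = "high"
    lo, hi = _SPECIES_RANGES[cls]
    return AbundanceCall(abundance=cls, species_consistent=lo <= species_at_site <= hi)


def regress(
    records: Sequence[RegionalRecord],
    x: str = "n_tribes",
    y: str = "n_patterns",
) -> RegressionResult:
    """OLS of pattern count on a diversity predictor, with R².

    ``x`` is ``n_tribes`` (phylogenetic-diversity proxy) or ``n_species``
    (alpha diversity); R² = 1 − SS_res/SS_tot.
    """
    if x not in ("n_tribes", "n_species"):
        raise ValueError("x must be 'n_tribes' or 'n_species'")
    if len(records) < 2:
        raise ValueError("regression needs at least 2 records")
    xs = np.array([getattr(r, x) for r in records], dtype=float)
    ys = np.array([getattr(r, y) for r in records], dtype=float)
    if np.ptp(xs) == 0:
        raise ValueError(f"degenerate fit: {x} is constant")
    fit = stats.linregress(xs, ys)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    resid = ys - (fit.intercept + fit.slope * xs)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=r2, n=len(records),
    )


def sensitivity_substitute(
    records: Sequence[RegionalRecord],
    region: str,
    new_n_species: int,
    x: str = "n_species",
) -> Tuple[RegressionResult, RegressionResult, float]:
    """Regression before/after substituting one region's species count.

    Returns (before, after, r2_ratio). Emulates asking how the fit changes
    when a described-species count is replaced by an estimate of the real
    fauna. A 2-record table is accepted but warned about.
    """
    names = [r.region for r in records]
    if region not in names:
        raise ValueError(f"unknown region {region!r}")
    if len(records) <= 2:
        import warnings

        warnings.warn("sensitivity on n <= 2 records is uninformative")
    before = regress(records, x=x)
    substituted = [
        replace(r, n_species=new_n_species) if r.region == region else r
        for r in records
    ]
    after = regress(substituted, x=x)
    ratio = after.r_squared / before.r_squared if before.r_squared > 0 else float("inf")
    return before, after, ratio


# ---------------------------------------------------------------------------
# I/O and plotting


def read_regional_table(path) -> List[RegionalRecord]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        ab = getattr(row, "abundance_class", None)
        if isinstance(ab, float) and np.isnan(ab):
            ab = None
        out.append(
            RegionalRecord(
                region=str(row.region), n_tribes=int(row.n_tribes),
                n_species=int(row.n_species), n_patterns=int(row.n_patterns),
                abundance_class=ab,
            )
        )
    return out


def write_regional_table(path, records: Iterable[RegionalRecord]) -> None:
    pd.DataFrame(
        [
            {
                "region": r.region, "n_tribes": r.n_tribes,
                "n_species": r.n_species, "n_patterns": r.n_patterns,
                "abundance_class": r.abundance_class or "",
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def plot_regional_panels(records: Sequence[RegionalRecord], path) -> None:
    """Three-panel scatter (tribes, species, patterns per region) as vector art."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    xs = [r.n_tribes for r in records]
    ys = [r.n_species for r in records]
    ps = [r.n_patterns for r in records]
    panels = [
        (xs, ps, "tribes (phylogenetic diversity)", "patterns"),
        (ys, ps, "species (alpha diversity)", "patterns"),
        (xs, ys, "tribes", "species"),
    ]
    for ax, (px, py, xl, yl) in zip(axes, panels):
        ax.scatter(px, py, color="#c23b22")
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
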