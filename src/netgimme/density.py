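"""Sign-split within/between-network density metrics.

Each directed non-AR edge of a subject's final graph is assigned to the
unordered pair of networks of its endpoint ROIs and split by the sign of
its coefficient, yielding 12 metrics: {DMN-DMN, SN-SN, FPN-FPN, DMN-SN,
SN-FPN, DMN-FPN} x {pos, neg}.  Autoregressive (lagged self) paths are
excluded throughout: every subject carries all of them by construction,
so they hold no between-subject information.

Two denominator modes are available.  Mode ``possible`` (the default)
divides each category's count by the number of admissible directed paths
in that category — within a network of size n there are 2 n (n-1)
(contemporaneous plus lagged non-self), and between networks of sizes
n1, n2 there are 4 n1 n2.  Mode ``total`` divides every count by the
subject's total number of non-AR edges, in which case the 12 values sum
to one whenever the graph is non-empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import NETWORK_LABELS, NetworkAtlas

#: canonical order of the six unordered network categories
CATEGORIES = ("DMN-DMN", "SN-SN", "FPN-FPN", "DMN-SN", "SN-FPN", "DMN-FPN")
#: canonical order of the 12 sign-split metrics
METRICS = tuple(f"{cat}_{sign}" for cat in CATEGORIES for sign in ("pos", "neg"))


def _category_of(net_a: str, net_b: str) -> str:
    if net_a == net_b:
        return f"{net_a}-{net_a}"
    order = {n: i for i, n in enumerate(NETWORK_LABELS)}
    a, b = sorted((net_a, net_b), key=order.get)
    return f"{a}-{b}"


def category_denominators(atlas: NetworkAtlas) -> dict[str, int]:
    """Admissible directed non-AR path counts per category."""
    sizes = {n: 0 for n in NETWORK_LABELS}
    sizes.update(atlas.network_sizes)
    den = {}
    for cat in CATEGORIES:
        a, b = cat.split("-")
        if a == b:
            n = sizes[a]
            den[cat] = 2 * n * (n - 1)
        else:
            den[cat] = 4 * sizes[a] * sizes[b]
    return den


@dataclass(frozen=True)
class DensityProfile:
    """One subject's 12 sign-split density metrics."""

    subject_id: str
    counts: dict[str, int]  # metric -> raw edge count
    values: dict[str, float]  # metric -> density
    denominators: dict[str, int]  # metric -> denominator used
    mode: str

    def as_series(self) -> pd.Series:
        return pd.Series({m: self.values[m] for m in METRICS}, name=self.subject_id)


def compute_density_profile(
    edges,
    atlas: NetworkAtlas,
    mode: str = "possible",
    subject_id: str = "",
) -> DensityProfile:
    """Densities from a subject's edge set.

    ``edges`` is an iterable of (source_idx, target_idx, lag, estimate).
    Lagged self-loops (AR paths) are ignored; a zero estimate is an
    error because its sign is undefined.
    """
    if mode not in ("possible", "total"):
        raise ValueError("mode must be 'possible' or 'total'")
    nets = atlas.networks_of_indices()
    counts = {m: 0 for m in METRICS}
    total = 0
    for s, t, lag, est in edges:
        if s == t:
            if lag == 0:
                raise ValueError("contemporaneous self-loop in edge set")
            continue  # AR-style self path never counts
        if est == 0:
            raise ValueError(f"edge ({s}->{t}, lag {lag}) has zero estimate; sign undefined")
        cat = _category_of(nets[s], nets[t])
        sign = "pos" if est > 0 else "neg"
        counts[f"{cat}_{sign}"] += 1
        total += 1

    if mode == "possible":
        cat_den = category_denominators(atlas)
        den = {m: cat_den[m.rsplit("_", 1)[0]] for m in METRICS}
    else:
        den = {m: total for m in METRICS}
    values = {m: (counts[m] / den[m] if den[m] > 0 else 0.0) for m in METRICS}
    return DensityProfile(
        subject_id=subject_id, counts=counts, values=values, denominators=den, mode=mode
    )


def density_table(profiles) -> pd.DataFrame:
    """Stack profiles into a subjects x 12 metrics table."""
    return pd.DataFrame([p.as_series() for p in profiles])


@dataclass(frozen=True)
class EligibilitySet:
    """Which metrics enter outcome models under the 25%-of-sample rule."""

    included: dict[str, bool]
    nonzero_counts: dict[str, int]
    threshold: float
    n_subjects: int

    @property
    def min_count(self) -> int:
        return math.ceil(self.threshold * self.n_subjects)

    def included_metrics(self) -> list[str]:
        return [m for m in METRICS if self.included[m]]


def eligible_metrics(table: pd.DataFrame, threshold: float = 0.25) -> EligibilitySet:
    """A metric is interpreted only if enough subjects have nonzero density.

    Inclusion requires at least ceil(threshold * N) subjects with a
    nonzero value (threshold 0.25: 13 of 49 qualifies, 12 does not).
    """
    n = len(table)
    if n < 1:
        raise ValueError("need at least one subject")
    need = math.ceil(threshold * n)
    counts = {m: int((table[m] != 0).sum()) for m in METRICS}
    return EligibilitySet(
        included={m: counts[m] >= need for m in METRICS},
        nonzero_counts=counts,
        threshold=threshold,
        n_subjects=n,
    )


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptives per metric: nonzero N, mean, SD, range."""
    rows = []
    for m in METRICS:
        v = table[m]
        rows.append(
            {
                "metric": m,
                "n_nonzero": int((v != 0).sum()),
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "min": v.min(),
                "max": v.max(),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def true_density_table(structure, mode: str = "possible") -> pd.DataFrame:
    """Density profiles computed from a TrueStructure's composite graphs."""
    profiles = []
    for sid in structure.subject_ids:
        edges = [
            (s, t, lag, coef)
            for s, t, lag, coef in structure.paths_for(sid)
            if not (lag == 1 and s == t)
        ]
        profiles.append(
            compute_density_profile(edges, structure.atlas, mode=mode, subject_id=sid)
        )
    return density_table(profiles)
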