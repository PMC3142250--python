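"""Lineage-through-time curves and the incomplete-sampling threshold.

A genus-level phylogeny samples one representative per genus, so deep nodes
are complete while shallow nodes are progressively undersampled.  Because
speciation within a monophyletic genus can only postdate the genus's stem
node, the species missing from each genus start "accumulating" at that stem
age.  The cumulative missing-species curve quantifies how unreliable the
LTT plot becomes toward the present, and a threshold age (where the missing
percentage first exceeds a tolerance, or where the single largest jump
occurs) bounds the window within which diversification analyses are
trustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import BranchingTimes, Chronogram

__all__ = [
    "LTTCurve",
    "MissingCurve",
    "ThresholdResult",
    "ltt",
    "ltt_ensemble",
    "missing_species_curve",
    "find_threshold",
    "read_richness_csv",
    "plot_ltt_with_missing",
]


@dataclass
class LTTCurve:
    """Lineage counts against age (descending ages, counts grow tip-ward).

    For a single tree this is the exact step function: ``counts[i]`` is the
    number of lineages at ``ages[i]``, which holds until the next younger
    listed age; the last entry is the window end.  For a
    posterior ensemble, ``counts`` is the per-grid-age mean and ``lower`` /
    ``upper`` hold the 2.5% / 97.5% percentile band.
    """

    ages: np.ndarray
    counts: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    @property
    def is_ensemble(self) -> bool:
        return self.lower is not None

    def to_frame(self) -> pd.DataFrame:
        data = {"age": self.ages, "lineages": self.counts}
        if self.is_ensemble:
            data["lower_2.5"] = self.lower
            data["upper_97.5"] = self.upper
        return pd.DataFrame(data)


def ltt(bt: BranchingTimes) -> LTTCurve:
    """Exact LTT step function of one set of branching times.

    Two lineages exist at the crown age; each younger branching time adds
    one.  The final count (``n_tips``) holds down to the window end.
    """
    ages = np.concatenate((bt.ages, [bt.window_end]))
    counts = np.append(np.arange(2, bt.n_tips + 1), bt.n_tips)
    return LTTCurve(ages=ages, counts=counts.astype(float))


def lineages_at(bt: BranchingTimes, age) -> np.ndarray:
    """Number of lineages at the given age(s): 1 before the crown, else
    2 + number of younger branching events."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    counts = 1.0 + np.sum(bt.ages[None, :] >= age[:, None], axis=1)
    counts[age > bt.crown_age] = 1.0
    return counts


def ltt_ensemble(trees, grid_size: int = 200) -> LTTCurve:
    """Mean LTT and 95% percentile band over a set of chronograms.

    The grid spans [0, max crown age]; trees younger than a grid age
    contribute a single (stem) lineage there.  Accepts chronograms or
    pre-extracted branching times.
    """
    bts = [t.branching_times() if isinstance(t, Chronogram) else t
           for t in trees]
    if len(bts) < 2:
        raise ValueError("need at least 2 trees for an ensemble")
    oldest = max(b.crown_age for b in bts)
    grid = np.linspace(oldest, 0.0, grid_size)
    counts = np.vstack([lineages_at(b, grid) for b in bts])
    return LTTCurve(
        ages=grid,
        counts=counts.mean(axis=0),
        lower=np.percentile(counts, 2.5, axis=0),
        upper=np.percentile(counts, 97.5, axis=0),
    )


@dataclass
class MissingCurve:
    """Cumulative missing species as a function of age.

    ``ages`` are the distinct stem ages (descending).  ``missing[i]`` and
    ``percent[i]`` give the cumulative count / percentage of the family
    total missing once every genus with stem age >= ``ages[i]`` is present.
    ``contributors[i]`` maps genus -> species added at that age.
    """

    ages: np.ndarray
    missing: np.ndarray
    percent: np.ndarray
    family_total: int
    contributors: list[dict]

    def percent_at(self, age: float) -> float:
        """Missing percentage at an age (genera with stem age >= age count)."""
        idx = np.searchsorted(-self.ages, -age, side="right")
        return float(self.percent[idx - 1]) if idx > 0 else 0.0

    @property
    def final_percent(self) -> float:
        return float(self.percent[-1]) if self.percent.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages,
            "missing_species": self.missing,
            "missing_percent": self.percent,
        })


def read_richness_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    required = {"genus", "total", "sampled"}
    if not required <= set(df.columns):
        raise ValueError(f"richness CSV needs columns {sorted(required)}")
    if (df["total"] < df["sampled"]).any() or (df["sampled"] < 0).any():
        raise ValueError("richness table needs total >= sampled >= 0")
    return df


def missing_species_curve(tree: Chronogram, richness: pd.DataFrame,
                          use_crown: bool = False) -> MissingCurve:
    """Cumulative missing-species curve from stem ages and genus richness.

    At age t the missing count is the sum of (total - sampled) over all
    genera whose stem age is >= t: once a genus lineage exists, all its
    unsampled species could in principle have arisen.  Genera with stem age
    exactly t count as already present (conservative).  ``use_crown`` is
    not meaningful for one-tip-per-genus trees and is reserved for trees
    with multiple tips per genus.
    """
    if use_crown:
        raise NotImplementedError(
            "crown-age variant requires multiple tips per genus")
    tab = richness.set_index("genus")
    missing_tips = [t for t in tree.tip_labels if t not in tab.index]
    if missing_tips:
        raise ValueError(f"tips absent from the richness table: {missing_tips}")
    if (tab.loc[tree.tip_labels, "total"] < tab.loc[tree.tip_labels, "sampled"]).any():
        raise ValueError("richness table needs total >= sampled")
    stems = tree.stem_ages()
    family_total = int(tab.loc[tree.tip_labels, "total"].sum())
    per_genus = {
        g: int(tab.loc[g, "total"] - tab.loc[g, "sampled"])
        for g in tree.tip_labels
    }
    by_age: dict[float, dict] = {}
    for g, age in stems.items():
        by_age.setdefault(float(age), {})[g] = per_genus[g]
    ages = np.array(sorted(by_age, reverse=True))
    increments = np.array([sum(by_age[a].values()) for a in ages], dtype=float)
    missing = np.cumsum(increments)
    percent = 100.0 * missing / family_total
    return MissingCurve(ages=ages, missing=missing, percent=percent,
                        family_total=family_total,
                        contributors=[by_age[a] for a in ages])


@dataclass
class ThresholdResult:
    age: float
    rule: str
    tolerance: float | None
    genus: str | None
    jump_percent: float | None
    warning: str | None = None


def find_threshold(curve: MissingCurve, rule: str = "tolerance",
                   tolerance: float = 15.0) -> ThresholdResult:
    """Locate the age beyond which sampling is too incomplete.

    rule "tolerance": the oldest age at which the missing percentage
    exceeds ``tolerance`` (percent of the family total).  rule "max-jump":
    the age of the single largest increment of the curve, reporting the
    genus responsible (the *Calamus*-style diagnostic).  If the tolerance
    is never exceeded the present (age 0) is returned with a warning.
    """
    if curve.ages.size == 0:
        raise ValueError("empty missing-species curve")
    if rule == "tolerance":
        over = np.nonzero(curve.percent > tolerance)[0]
        if over.size == 0:
            return ThresholdResult(
                age=0.0, rule=rule, tolerance=tolerance, genus=None,
                jump_percent=None,
                warning=f"missing percentage never exceeds {tolerance}%")
        idx = int(over[0])
        contribs = curve.contributors[idx]
        genus = max(contribs, key=contribs.get) if contribs else None
        return ThresholdResult(age=float(curve.ages[idx]), rule=rule,
                               tolerance=tolerance, genus=genus,
                               jump_percent=None)
    if rule == "max-jump":
        increments = np.diff(np.concatenate(([0.0], curve.percent)))
        idx = int(np.argmax(increments))
        contribs = curve.contributors[idx]
        genus = max(contribs, key=contribs.get) if contribs else None
        return ThresholdResult(age=float(curve.ages[idx]), rule=rule,
                               tolerance=None, genus=genus,
                               jump_percent=float(increments[idx]))
    raise ValueError(f"unknown rule {rule!r}; use 'tolerance' or 'max-jump'")


def plot_ltt_with_missing(ltt_curve: LTTCurve,
                          missing: MissingCurve | None = None,
                          threshold: float | None = None,
                          ax=None):
    """Semilogarithmic LTT plot, optionally with the missing-taxa curve."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(ltt_curve.ages, ltt_curve.counts, where="pre", label="lineages")
    if ltt_curve.is_ensemble:
        ax.fill_between(ltt_curve.ages, ltt_curve.lower, ltt_curve.upper,
                        alpha=0.25, step="pre", label="95% band")
    ax.set_yscale("log")
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("lineages")
    ax.invert_xaxis()
    if missing is not None:
        ax2 = ax.twinx()
        ax2.step(missing.ages, missing.percent, where="post", color="grey",
                 label="% missing")
        ax2.set_ylabel("missing species (%)")
    if threshold is not None:
        ax.axvline(threshold, color="black", lw=1)
    return ax
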