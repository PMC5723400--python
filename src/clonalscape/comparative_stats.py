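"""Cross-species and spatial comparisons of clonal richness.

Species are compared nonparametrically (Kruskal-Wallis on medians plus
Mood's median test on the distribution around the grand median), and
latitudinal / between-species spatial patterns are assessed with Pearson
correlations. Richness values live in [0, 1] and the site is the unit of
replication throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SpeciesComparison:
    kruskal_H: float
    kruskal_p: float
    median_chi2: float
    median_p: float
    medians: dict


def species_comparison(groups: dict) -> SpeciesComparison:
    """Compare richness distributions across species.

    ``groups`` maps species name -> vector of per-site R. Kruskal-Wallis
    (tie-corrected) tests for a location shift in the medians; Mood's
    median test classifies values against the grand median to test whether
    the distributions differ. Completely tied pooled data (zero variance
    in ranks) is reported as H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two species groups")
    vectors = []
    for name, v in groups.items():
        v = np.asarray(v, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs >= 2 observations")
        vectors.append(v)
    pooled = np.concatenate(vectors)
    if np.all(pooled == pooled[0]):
        h, hp = 0.0, 1.0
        chi2, mp = 0.0, 1.0
    else:
        h, hp = stats.kruskal(*vectors)
        chi2, mp, _, _ = stats.median_test(*vectors)
    return SpeciesComparison(
        kruskal_H=float(h), kruskal_p=float(hp),
        median_chi2=float(chi2), median_p=float(mp),
        medians={k: float(np.median(np.asarray(v, dtype=float)))
                 for k, v in groups.items()},
    )


def latitude_correlation(
    latitude, richness, use_absolute: bool = True
) -> "tuple[float, float]":
    """Pearson correlation of per-site R with latitude.

    The study spans the southern hemisphere, so latitude defaults to its
    absolute value (distance from the equator); pass
    ``use_absolute=False`` for signed latitude. p is two-sided from the t
    distribution with n - 2 df.
    """
    lat = np.asarray(latitude, dtype=float)
    r_vec = np.asarray(richness, dtype=float)
    if use_absolute:
        lat = np.abs(lat)
    if len(lat) < 3:
        raise ValueError(f"need >= 3 sites, got {len(lat)}")
    if np.std(lat) == 0 or np.std(r_vec) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(lat, r_vec)
    return float(res.statistic), float(res.pvalue)


def cooccurrence_correlation(richness_a, richness_b) -> "tuple[float, float]":
    """Pearson correlation of R between two species at shared sites."""
    a = np.asarray(richness_a, dtype=float)
    b = np.asarray(richness_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError(f"need >= 3 shared sites, got {len(a)}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def comparison_report(richness: pd.DataFrame) -> dict:
    """Run every comparison the richness table supports.

    Expects columns site_id, species, latitude, R. Latitude correlations
    run per species; the between-species correlation runs for every
    species pair with >= 3 shared sites.
    """
    groups = {
        sp: sub["R"].to_numpy()
        for sp, sub in richness.groupby("species")
        if len(sub) >= 2
    }
    report = {"species_comparison": species_comparison(groups)}
    lat = {}
    for sp, sub in richness.groupby("species"):
        if len(sub) >= 3 and sub["R"].nunique() > 1:
            lat[sp] = latitude_correlation(sub["latitude"], sub["R"])
    report["latitude"] = lat
    pairs = {}
    species = sorted(richness["species"].unique())
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            a = richness[richness["species"] == species[i]].set_index("site_id")["R"]
            b = richness[richness["species"] == species[j]].set_index("site_id")["R"]
            shared = a.index.intersection(b.index)
            if len(shared) >= 3:
                try:
                    pairs[(species[i], species[j])] = cooccurrence_correlation(
                        a.loc[shared], b.loc[shared]
                    )
                except ValueError:
                    continue
    report["cooccurrence"] = pairs
    return report
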