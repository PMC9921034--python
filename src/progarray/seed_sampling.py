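"""Seedling resampling schemes and allele-capture evaluation.

Two questions about seed collections are answered by resampling genotyped
progeny arrays:

* **Within a site** — how should eight seeds be split among maternal lines?
  The schemes (1 mother x 8 seeds ... 8 mothers x 1 seed) are compared by the
  mean pairwise Euclidean distance among the drawn seedlings, with the
  mothers' own mean pairwise distance as the reference panel value.
* **Among sites** — how many collection sites are needed to capture the
  alleles segregating in the wild adults?  Replicate draws of one seedling
  per maternal line per site are scored by the proportion of reference-panel
  alleles above a frequency threshold that appear in the subsample.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import FamilyMap, GenotypeMatrix
from .popgen_stats import euclidean_distances, mean_offdiag

logger = logging.getLogger(__name__)

__all__ = [
    "WithinSiteScheme",
    "AmongSiteScheme",
    "within_site_resample",
    "among_site_resample",
    "allele_capture",
]

#: (n_mothers, seeds_per_mother) splits of an eight-seed collection
DEFAULT_SPLITS: tuple[tuple[int, int], ...] = ((1, 8), (2, 4), (4, 2), (8, 1))


@dataclass
class WithinSiteScheme:
    splits: tuple[tuple[int, int], ...] = DEFAULT_SPLITS
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for m, k in self.splits:
            if m * k != 8:
                raise ValueError(f"split {m}x{k} does not draw 8 seedlings")


@dataclass
class AmongSiteScheme:
    n_sites_range: Sequence[int] = ()
    lines_per_site: int = 8
    n_replicates: int = 100
    maf_thresholds: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05)
    reference_panel: str = "mothers"      # "mothers" | "all_wild"
    enumerate_combinations: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.maf_thresholds:
            if not 0.0 < t <= 0.5:
                raise ValueError(f"threshold {t} outside (0, 0.5]")


# ---------------------------------------------------------------------------
# Within-site schemes
# ---------------------------------------------------------------------------

def within_site_resample(
    matrix: GenotypeMatrix,
    family_map: FamilyMap,
    scheme: WithinSiteScheme | None = None,
    sites: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Replicate within-site draws under each (mothers x seeds) split.

    Mothers are drawn without replacement, then seedlings without replacement
    within each drawn line.  Infeasible site/split combinations (too few
    lines with enough progeny) are skipped with a logged reason.  Returns one
    row per site x split x replicate with the subsample's mean pairwise
    distance, plus one ``mothers_panel`` row per site.
    """
    scheme = scheme or WithinSiteScheme()
    rng = np.random.default_rng(scheme.seed)
    rows = []
    for site in (sites if sites is not None else family_map.sites):
        lines = family_map.lines_for_site(site)
        mother_ids = family_map.mothers_for_site(site)
        if len(mother_ids) >= 2:
            panel = mean_offdiag(euclidean_distances(matrix, mother_ids))
            rows.append(
                {"site": site, "scheme": "mothers_panel", "n_mothers": len(mother_ids),
                 "seeds_per_mother": 0, "replicate": -1, "mean_distance": panel}
            )
        for n_m, n_s in scheme.splits:
            eligible = sorted(m for m, prog in lines.items() if len(prog) >= n_s)
            if len(eligible) < n_m:
                logger.info(
                    "site %s: scheme %dx%d skipped (%d eligible lines, need %d)",
                    site, n_m, n_s, len(eligible), n_m,
                )
                continue
            for rep in range(scheme.n_replicates):
                chosen = rng.choice(eligible, size=n_m, replace=False)
                draw: list[str] = []
                for m in chosen:
                    draw.extend(rng.choice(lines[m], size=n_s, replace=False))
                d = mean_offdiag(euclidean_distances(matrix, draw))
                rows.append(
                    {"site": site, "scheme": f"{n_m}x{n_s}", "n_mothers": n_m,
                     "seeds_per_mother": n_s, "replicate": rep, "mean_distance": d}
                )
    columns = ["site", "scheme", "n_mothers", "seeds_per_mother", "replicate",
               "mean_distance"]
    if not rows:
        logger.warning("no scheme feasible at any site; empty result")
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Allele capture
# ---------------------------------------------------------------------------

def allele_capture(
    reference: GenotypeMatrix,
    subsample: GenotypeMatrix,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Proportion of reference alleles above each frequency threshold present
    in the subsample.

    Both alleles of a polymorphic locus count separately.  An allele is
    "present" when at least one non-missing subsample genotype carries it;
    no error-rate adjustment is applied (alleles rarer than the lowest
    threshold are never scored, which is the guard against miscalls).
    """
    ref_dos = reference.dosages()
    called = (~np.isnan(ref_dos)).sum(axis=0)
    if (called == 0).all():
        raise ValueError("reference panel has no called genotypes")
    with np.errstate(invalid="ignore"):
        q = np.nansum(ref_dos, axis=0) / (2.0 * np.maximum(called, 1))
    q = np.where(called > 0, q, np.nan)
    poly = (q > 0.0) & (q < 1.0)

    sub = subsample.subset(loci=reference.locus_ids)
    sub_dos = sub.dosages()
    alt_seen = np.nansum(sub_dos >= 1.0, axis=0) > 0
    ref_seen = np.nansum(sub_dos <= 1.0, axis=0) > 0

    rows = []
    for t in thresholds:
        alt_q = poly & (q >= t)
        ref_q = poly & (1.0 - q >= t)
        n_ref_alleles = int(alt_q.sum() + ref_q.sum())
        n_cap = int((alt_q & alt_seen).sum() + (ref_q & ref_seen).sum())
        rows.append(
            {
                "threshold": float(t),
                "n_reference_alleles": n_ref_alleles,
                "n_captured": n_cap,
                "proportion": (n_cap / n_ref_alleles) if n_ref_alleles else np.nan,
            }
        )
    return pd.DataFrame(rows)


def among_site_resample(
    matrix: GenotypeMatrix,
    family_map: FamilyMap,
    reference: GenotypeMatrix,
    scheme: AmongSiteScheme | None = None,
) -> pd.DataFrame:
    """Allele capture of among-site seedling subsamples.

    For each number of sites and replicate: draw a site combination (uniformly
    at random, or enumerate all combinations when
    ``scheme.enumerate_combinations``), draw one seedling from each of up to
    ``lines_per_site`` maternal lines per site (all available lines when a
    site has fewer, logged), and score allele capture against the reference
    panel at each threshold.
    """
    scheme = scheme or AmongSiteScheme()
    rng = np.random.default_rng(scheme.seed)
    sites = family_map.sites
    n_sites_range = list(scheme.n_sites_range) or list(range(1, len(sites) + 1))
    if max(n_sites_range) > len(sites):
        raise ValueError(
            f"requested {max(n_sites_range)} sites but only {len(sites)} available"
        )
    site_lines = {s: family_map.lines_for_site(s) for s in sites}
    for s in sites:
        if len(site_lines[s]) < scheme.lines_per_site:
            logger.info(
                "site %s has %d maternal lines (< %d); drawing all of them",
                s, len(site_lines[s]), scheme.lines_per_site,
            )

    rows = []
    for n_sites in n_sites_range:
        if scheme.enumerate_combinations:
            combos = list(itertools.combinations(sites, n_sites))
        else:
            combos = [
                tuple(rng.choice(sites, size=n_sites, replace=False))
                for _ in range(scheme.n_replicates)
            ]
        for rep, combo in enumerate(combos):
            draw: list[str] = []
            for site in combo:
                lines = site_lines[site]
                mothers = sorted(lines)
                if len(mothers) > scheme.lines_per_site:
                    mothers = list(
                        rng.choice(mothers, size=scheme.lines_per_site, replace=False)
                    )
                for m in mothers:
                    draw.append(str(rng.choice(lines[m])))
            cap = allele_capture(reference, matrix.subset(samples=draw),
                                 scheme.maf_thresholds)
            cap["n_sites"] = n_sites
            cap["replicate"] = rep
            cap["site_set"] = ",".join(combo)
            rows.append(cap)
    return pd.concat(rows, ignore_index=True)
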