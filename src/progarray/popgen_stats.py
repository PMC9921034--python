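"""Diversity, F-statistics, kinship, genetic distance and clone detection.

Estimators operate on dosage matrices (0/1/2, NaN missing) grouped into
populations.  Conventions:

* Ho is the per-locus fraction of heterozygous calls among non-missing calls,
  averaged over loci; He is Nei's gene diversity 2*p*q with the small-sample
  correction 2n/(2n-1), averaged over loci (monomorphic loci contribute 0).
* F_IS is the multilocus ratio of averages 1 - mean(Ho_l)/mean(He_l), which is
  stabler at low-diversity loci than averaging per-locus ratios.
* Pairwise F_ST is Weir & Cockerham's (1984) theta as a multilocus
  ratio-of-sums of the a/b/c variance components.
* Kinship is the method-of-moments identity-by-descent coefficient
  phi = E[(x - 2p)(y - 2p) / (4 p (1 - p))] with externally supplied allele
  frequencies (e.g. estimated from wild-sampled mothers), so that
  phi ~ 0.25 for outbred parent-offspring and 0.125 for half-sibs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix
from .synthetic_data import AlleleFreqTable

EARTH_RADIUS_KM = 6371.0088


class PopgenError(ValueError):
    pass


@dataclass
class DiversityResult:
    """Per-population diversity plus per-pair differentiation."""

    per_population: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_pair: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Heterozygosity and F_IS
# ---------------------------------------------------------------------------

def _locus_ho_he(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Ho, bias-corrected He and non-missing count for one population."""
    called = ~np.isnan(dos)
    n = called.sum(axis=0)
    if (n == 0).any():
        raise PopgenError("locus with no non-missing calls in population")
    ho = np.nansum(dos == 1.0, axis=0) / n
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(dos, axis=0) / (2.0 * n)
    he = 2.0 * p_alt * (1.0 - p_alt)
    corr = np.where(n > 0, 2.0 * n / np.maximum(2.0 * n - 1.0, 1.0), 1.0)
    return ho, he * corr, n


def heterozygosity(
    matrix: GenotypeMatrix,
    populations: Mapping[str, Sequence[str]],
    bias_correction: bool = True,
) -> DiversityResult:
    """Observed and expected heterozygosity per population."""
    rows = {}
    for pop, samples in populations.items():
        if len(samples) == 0:
            raise PopgenError(f"population {pop!r} is empty")
        dos = matrix.dosages(samples)
        ho, he, n = _locus_ho_he(dos)
        if not bias_correction:
            corr = 2.0 * n / np.maximum(2.0 * n - 1.0, 1.0)
            he = he / corr
        rows[pop] = {"Ho": float(ho.mean()), "He": float(he.mean()),
                     "n_samples": len(samples), "n_loci": matrix.n_loci}
    return DiversityResult(
        per_population=pd.DataFrame(rows).T,
        provenance={"he_bias_correction": bias_correction},
    )


def fis(
    matrix: GenotypeMatrix,
    populations: Mapping[str, Sequence[str]],
) -> DiversityResult:
    """Multilocus F_IS = 1 - mean(Ho)/mean(He) per population.

    All-monomorphic populations yield NaN with a warning recorded in the
    provenance block rather than an exception.
    """
    res = heterozygosity(matrix, populations)
    warn = []
    out = res.per_population
    vals = []
    for pop in out.index:
        ho, he = out.loc[pop, "Ho"], out.loc[pop, "He"]
        if he <= 0:
            warn.append(f"{pop}: all loci monomorphic, F_IS undefined")
            vals.append(np.nan)
        else:
            vals.append(1.0 - ho / he)
    out["Fis"] = vals
    res.provenance["warnings"] = warn
    return res


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(
    dosage_blocks: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components (a, a+b+c).

    ``dosage_blocks`` holds one samples x loci array per population; missing
    calls reduce the per-locus sample size of their population.
    """
    r = len(dosage_blocks)
    n_i = np.stack([(~np.isnan(b)).sum(axis=0) for b in dosage_blocks])  # r x L
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nansum(b, axis=0) for b in dosage_blocks]) / (2.0 * n_i)
        h_i = np.stack([np.nansum(b == 1.0, axis=0) for b in dosage_blocks]) / n_i

    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    nc = (nsum - (n_i ** 2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / nsum
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / nsum

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    usable = (pbar > 0) & (pbar < 1) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return np.where(usable, a, 0.0), np.where(usable, a + b + c, 0.0)


def weir_cockerham_fst(dosage_blocks: Sequence[np.ndarray]) -> float:
    """Multilocus theta: ratio of sums of per-locus variance components."""
    a, abc = _wc_components(dosage_blocks)
    denom = abc.sum()
    if denom == 0:
        raise PopgenError("no polymorphic loci for F_ST")
    return float(a.sum() / denom)


def pairwise_fst(
    matrix: GenotypeMatrix,
    populations: Mapping[str, Sequence[str]],
    coords: Mapping[str, tuple[float, float]] | None = None,
) -> DiversityResult:
    """Weir-Cockerham F_ST for every population pair (optionally with
    great-circle distances when coordinates are given)."""
    pops = list(populations)
    for pop in pops:
        if len(populations[pop]) < 2:
            raise PopgenError(f"population {pop!r} has fewer than 2 samples")
    blocks = {p: matrix.dosages(populations[p]) for p in pops}
    rows = []
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            est = weir_cockerham_fst([blocks[pa], blocks[pb]])
            row = {"pop_a": pa, "pop_b": pb, "fst": est}
            if coords is not None:
                row["distance_km"] = haversine_km(coords[pa], coords[pb])
            rows.append(row)
    return DiversityResult(
        per_pair=pd.DataFrame(rows),
        provenance={"fst_estimator": "Weir-Cockerham 1984 ratio-of-sums"},
    )


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------

def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) points in degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def isolation_by_distance(diversity: DiversityResult) -> dict:
    """Least-squares slope and Spearman correlation of F_ST against distance."""
    df = diversity.per_pair
    if len(df) < 3:
        raise PopgenError("need at least 3 population pairs")
    if "distance_km" not in df.columns:
        raise PopgenError("per-pair distances missing; supply coordinates")
    d = df["distance_km"].to_numpy(dtype=float)
    f = df["fst"].to_numpy(dtype=float)
    if np.allclose(d, d[0]):
        raise PopgenError("all site pairs at identical distance; geometry degenerate")
    slope, intercept, r, p_lin, _ = stats.linregress(d, f)
    rho, p_rho = stats.spearmanr(d, f)
    return {
        "slope_per_km": float(slope),
        "intercept": float(intercept),
        "spearman_rho": float(rho),
        "spearman_p": float(p_rho),
        "n_pairs": int(len(df)),
    }


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipResult:
    per_pair: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def kinship_mom(
    matrix: GenotypeMatrix,
    freqs: AlleleFreqTable,
    pairs: Sequence[tuple[str, str]],
    population: str,
    labels: Sequence[str] | None = None,
) -> KinshipResult:
    """Method-of-moments IBD kinship for sample pairs.

    Uses the supplied population allele frequencies; loci fixed in that
    population (freq 0 or 1) and pairwise-missing loci are excluded.
    """
    q = freqs.alt_freqs(population).reindex(matrix.locus_ids).to_numpy(dtype=float)
    usable_locus = (q > 0.0) & (q < 1.0)
    dos = matrix.genotypes
    rows = []
    for idx, (sa, sb) in enumerate(pairs):
        x = dos.loc[sa].to_numpy(dtype=float)
        y = dos.loc[sb].to_numpy(dtype=float)
        ok = usable_locus & ~np.isnan(x) & ~np.isnan(y)
        if not ok.any():
            raise PopgenError(f"no usable loci for pair ({sa}, {sb})")
        num = (x[ok] - 2 * q[ok]) * (y[ok] - 2 * q[ok])
        phi = float(np.mean(num / (4 * q[ok] * (1 - q[ok]))))
        rows.append(
            {
                "sample_a": sa,
                "sample_b": sb,
                "kinship": phi,
                "n_loci": int(ok.sum()),
                "label": labels[idx] if labels is not None else "",
            }
        )
    return KinshipResult(
        pd.DataFrame(rows),
        provenance={"estimator": "moment IBD with supplied frequencies",
                    "population": population},
    )


# ---------------------------------------------------------------------------
# Distances and isogenic lines
# ---------------------------------------------------------------------------

def euclidean_distances(
    matrix: GenotypeMatrix, samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Euclidean distance on dosage vectors.

    Missing calls are handled pairwise-complete with rescaling
    d = sqrt(L / |C| * sum_C (x_i - y_i)^2) over the shared called set C.
    """
    ids = list(samples) if samples is not None else matrix.sample_ids
    if len(ids) < 2:
        raise PopgenError("need at least 2 samples")
    dos = matrix.dosages(ids)
    L = dos.shape[1]
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
            m = ok.sum()
            if m == 0:
                raise PopgenError(f"pair ({ids[i]}, {ids[j]}) shares no called loci")
            d = np.sqrt(L / m * np.sum((dos[i, ok] - dos[j, ok]) ** 2))
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


def mean_offdiag(dist: pd.DataFrame) -> float:
    """Mean of the off-diagonal entries of a square distance matrix."""
    a = dist.to_numpy(dtype=float)
    n = a.shape[0]
    if n < 2:
        raise PopgenError("need at least 2 samples")
    return float(a[np.triu_indices(n, k=1)].mean())


def isogenic_lines(
    matrix: GenotypeMatrix,
    samples: Sequence[str] | None = None,
    identity_threshold: float = 0.99,
) -> list[list[str]]:
    """Partition samples into (near-)identical groups.

    Single-linkage grouping on the proportion of identical non-missing calls:
    two samples join a group when their identity-in-state proportion meets the
    threshold, directly or through intermediates.  Detects isogenic lines
    (e.g. repeatedly selfed descendants of one founder, or clones).
    """
    ids = list(samples) if samples is not None else matrix.sample_ids
    if not ids:
        return []
    dos = matrix.dosages(ids)
    n = len(ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
            if not ok.any():
                continue
            identity = np.mean(dos[i, ok] == dos[j, ok])
            if identity >= identity_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, s in enumerate(ids):
        groups.setdefault(find(i), []).append(s)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))
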