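"""Simulation of landscape- and family-structured SNP genotype data with known truth.

The generator emulates a reduced-representation SNP survey of a plant species
sampled as (a) adults spread over a multi-population landscape and (b)
mother plants plus seed progeny at a subset of sites:

* **Landscape**: a hierarchical island model.  Each locus has an ancestral
  alternate-allele frequency p; each population draws its own frequency from a
  Beta distribution with mean p and variance ``fst_target * p * (1 - p)``, so
  ``fst_target`` is the expected Wright F_ST.  Adult genotypes are drawn with
  an equilibrium inbreeding coefficient F: P(het) = 2pq(1-F).
* **Families**: each progeny is selfed with probability s (two independent
  maternal gametes) or outcrossed (one maternal gamete plus a pollen allele
  drawn from the population allele frequency).
* **Noise**: independent per-allele miscalls with probability epsilon, plus
  random masking of calls, plus DArT-style per-locus metadata (reproducibility
  scores, multi-SNP clone ids, call rates) to exercise the QC filters.

Everything is driven by explicit seeds; identical configs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import FamilyMap, GenotypeMatrix

__all__ = [
    "LandscapeConfig",
    "FamilyDesign",
    "NoiseModel",
    "generate_landscape",
    "generate_families",
    "simulate_progeny_dosages",
    "inject_dart_metadata",
    "AlleleFreqTable",
]


class AlleleFreqTable:
    """Per-population, per-locus reference-allele frequencies.

    Stored as a populations x loci DataFrame of *alternate*-allele
    frequencies internally (the dosage orientation), exposed both ways.
    """

    def __init__(self, alt_freq: pd.DataFrame, n_samples: pd.Series):
        if ((alt_freq.to_numpy() < 0) | (alt_freq.to_numpy() > 1)).any():
            raise ValueError("allele frequencies outside [0, 1]")
        self._alt = alt_freq
        self.n_samples = n_samples

    @property
    def populations(self) -> list[str]:
        return list(self._alt.index)

    @property
    def loci(self) -> list[str]:
        return list(self._alt.columns)

    def alt_freqs(self, population: str) -> pd.Series:
        return self._alt.loc[population]

    def ref_freqs(self, population: str) -> pd.Series:
        return 1.0 - self._alt.loc[population]

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: one row per (population, locus) with ref_freq + n."""
        long = self._alt.stack().rename("alt_freq").reset_index()
        long.columns = ["population", "locus", "alt_freq"]
        long["ref_freq"] = 1.0 - long["alt_freq"]
        long["n_samples"] = long["population"].map(self.n_samples).astype(int)
        return long

    @staticmethod
    def from_matrix(
        matrix: GenotypeMatrix, populations: dict[str, Sequence[str]]
    ) -> "AlleleFreqTable":
        """Estimate frequencies from observed dosages per population."""
        rows, ns = {}, {}
        for pop, samples in populations.items():
            dos = matrix.dosages(samples)
            with np.errstate(invalid="ignore"):
                rows[pop] = np.nanmean(dos, axis=0) / 2.0
            ns[pop] = len(samples)
        freq = pd.DataFrame(rows, index=matrix.locus_ids).T
        return AlleleFreqTable(freq, pd.Series(ns))


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Island-model landscape.

    ``maf_distribution`` is ``("uniform", lo, hi)`` or ``("beta", a, b)`` for
    the ancestral alternate-allele frequency; ``inbreeding_f`` may be a scalar
    applied to all populations or one value per population.
    """

    n_populations: int = 8
    n_loci: int = 2000
    maf_distribution: tuple = ("uniform", 0.1, 0.5)
    fst_target: float = 0.3
    inbreeding_f: float | Sequence[float] = 0.0
    n_adults_per_pop: int = 6
    coords: Sequence[tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError(f"fst_target={self.fst_target} outside [0, 1)")
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if self.n_populations <= 0:
            raise ValueError("n_populations must be positive")
        f = np.atleast_1d(np.asarray(self.inbreeding_f, dtype=float))
        if ((f < -1) | (f > 1)).any():
            raise ValueError("inbreeding_f outside [-1, 1]")


@dataclass
class FamilyDesign:
    """Mothers-plus-progeny design: 10 mothers per site, 7 with 3 progeny
    each and 3 with 10 progeny each by default."""

    n_mothers_per_site: int = 10
    lines_small: int = 7
    progeny_small: int = 3
    lines_large: int = 3
    progeny_large: int = 10

    def __post_init__(self) -> None:
        counts = (self.n_mothers_per_site, self.lines_small, self.progeny_small,
                  self.lines_large, self.progeny_large)
        if any(c <= 0 for c in counts):
            raise ValueError("all design counts must be positive")
        if self.lines_small + self.lines_large != self.n_mothers_per_site:
            raise ValueError("lines_small + lines_large must equal n_mothers_per_site")

    def progeny_counts(self) -> list[int]:
        return [self.progeny_small] * self.lines_small + \
               [self.progeny_large] * self.lines_large

    @property
    def n_progeny(self) -> int:
        return sum(self.progeny_counts())


@dataclass
class NoiseModel:
    """Genotyping noise: per-allele miscall rate, missingness and per-locus
    reproducibility metadata."""

    error_rate_epsilon: float = 0.005
    locus_missing_rate: float = 0.05
    sample_missing_rate: float = 0.0
    reproducibility_distribution: tuple = ("point", 1.0)
    fraction_multi_snp_clones: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate_epsilon < 0.5:
            raise ValueError("error_rate_epsilon outside [0, 0.5)")
        for name in ("locus_missing_rate", "sample_missing_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} outside [0, 1)")
        if not 0.0 <= self.fraction_multi_snp_clones <= 1.0:
            raise ValueError("fraction_multi_snp_clones outside [0, 1]")


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

def _draw_spec(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size)
    if kind == "beta":
        return rng.beta(spec[1], spec[2], size)
    if kind == "point":
        return np.full(size, float(spec[1]))
    raise ValueError(f"unknown distribution spec {spec!r}")


def _genotypes_from_freqs(
    rng: np.random.Generator, q: np.ndarray, f: float, n: int
) -> np.ndarray:
    """Draw n genotypes per locus with alt freq q and inbreeding f.

    P(dosage 2) = q^2 + f*p*q, P(1) = 2pq(1-f), P(0) = p^2 + f*p*q; for f < 0
    the heterozygote excess is capped where any class probability would go
    negative.
    """
    p = 1.0 - q
    p2 = np.clip(p * p + f * p * q, 0.0, 1.0)
    h = np.clip(2 * p * q * (1 - f), 0.0, 1.0)
    tot = p2 + h + np.clip(q * q + f * p * q, 0.0, 1.0)
    p2, h = p2 / tot, h / tot
    u = rng.random((n, q.size))
    return np.where(u < p2, 0.0, np.where(u < p2 + h, 1.0, 2.0))


def generate_landscape(
    config: LandscapeConfig,
) -> tuple[GenotypeMatrix, AlleleFreqTable, dict[str, list[str]]]:
    """Simulate adults across an island-model landscape.

    Returns the adult genotype matrix, the truth allele-frequency table
    (population-specific frequencies the genotypes were drawn from) and the
    population -> sample-id map.
    """
    rng = np.random.default_rng(config.seed)
    k, L = config.n_populations, config.n_loci
    anc = _draw_spec(rng, config.maf_distribution, L)
    anc = np.clip(anc, 1e-6, 1 - 1e-6)

    fst = config.fst_target
    if fst == 0.0:
        pop_q = np.tile(anc, (k, 1))
    else:
        c = (1.0 - fst) / fst  # Beta(a, b), a+b = c => var = fst*p*(1-p)
        a = np.maximum(anc * c, 1e-8)
        b = np.maximum((1.0 - anc) * c, 1e-8)
        pop_q = rng.beta(a[None, :].repeat(k, 0), b[None, :].repeat(k, 0))

    fvals = np.broadcast_to(
        np.atleast_1d(np.asarray(config.inbreeding_f, dtype=float)), (k,)
    ) if np.ndim(config.inbreeding_f) else np.full(k, float(config.inbreeding_f))

    pops = [f"P{i + 1:02d}" for i in range(k)]
    loci = [f"L{j + 1:05d}" for j in range(L)]
    blocks, sample_ids, pop_map = [], [], {}
    for i, pop in enumerate(pops):
        g = _genotypes_from_freqs(rng, pop_q[i], fvals[i], config.n_adults_per_pop)
        blocks.append(g)
        ids = [f"{pop}_A{j + 1:03d}" for j in range(config.n_adults_per_pop)]
        sample_ids.extend(ids)
        pop_map[pop] = ids

    matrix = GenotypeMatrix.from_arrays(np.vstack(blocks), sample_ids, loci)
    freqs = AlleleFreqTable(
        pd.DataFrame(pop_q, index=pops, columns=loci),
        pd.Series({p: config.n_adults_per_pop for p in pops}),
    )
    if config.coords is not None:
        if len(config.coords) != k:
            raise ValueError("coords length must equal n_populations")
        coords = {p: tuple(map(float, c)) for p, c in zip(pops, config.coords)}
    else:
        # jittered grid over a ~300 km box; deterministic under the seed
        side = int(np.ceil(np.sqrt(k)))
        coords = {
            p: (150.0 + (i % side) * 1.0 + rng.uniform(-0.2, 0.2),
                -35.0 + (i // side) * 1.0 + rng.uniform(-0.2, 0.2))
            for i, p in enumerate(pops)
        }
    matrix.site_coords = coords  # convenience attribute used by pipeline
    return matrix, freqs, pop_map


# ---------------------------------------------------------------------------
# Progeny generation
# ---------------------------------------------------------------------------

def _maternal_gametes(rng: np.random.Generator, mother: np.ndarray) -> np.ndarray:
    """One allele (0/1 = ref/alt) per locus from Mendelian segregation."""
    g = np.where(mother == 2.0, 1.0, 0.0)
    het = mother == 1.0
    g[het] = rng.integers(0, 2, het.sum()).astype(float)
    return g


def simulate_progeny_dosages(
    mother: np.ndarray,
    q_alt: np.ndarray,
    selfed: bool,
    rng: np.random.Generator,
    epsilon: float = 0.0,
) -> np.ndarray:
    """Simulate one progeny's dosage vector from a mother's dosages.

    Selfed progeny receive two independent maternal gametes; outcrossed
    progeny receive one maternal gamete plus a pollen allele ~ Bernoulli(q_alt).
    Per-allele miscalls are applied at rate ``epsilon``.  Loci where the
    mother's call is missing come out missing.
    """
    mother = np.asarray(mother, dtype=float)
    ok = ~np.isnan(mother)
    dos = np.full(mother.shape, np.nan)
    g1 = _maternal_gametes(rng, np.where(ok, mother, 0.0))
    if selfed:
        g2 = _maternal_gametes(rng, np.where(ok, mother, 0.0))
    else:
        g2 = (rng.random(mother.size) < np.asarray(q_alt, dtype=float)).astype(float)
    true = g1 + g2
    if epsilon > 0:
        alt_flips = rng.binomial(true.astype(int), epsilon)
        ref_flips = rng.binomial((2 - true).astype(int), epsilon)
        true = true - alt_flips + ref_flips
    dos[ok] = true[ok]
    return dos


def generate_families(
    adults: GenotypeMatrix,
    design: FamilyDesign,
    selfing_rates: float | Sequence[float],
    truth_freqs: AlleleFreqTable,
    noise: NoiseModel,
    seed: int,
    site: str | None = None,
    species: str = "SpA",
    mother_ids: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, FamilyMap, pd.DataFrame]:
    """Simulate a progeny array for one site.

    ``selfing_rates`` is a scalar site-level rate or one value per progeny (in
    design order).  Each progeny is wholly selfed with its probability s, else
    outcrossed to the population pollen pool.  Returns the mothers+progeny
    matrix, the family map, and the truth table with columns
    ``progeny_id, mother_id, line, s_assigned, selfed``.

    Noise (allele miscalls and masking) applies to progeny calls; the mother
    rows are carried through as observed.
    """
    rng = np.random.default_rng(seed)
    site = site or truth_freqs.populations[0]
    if site not in truth_freqs.populations:
        raise ValueError(f"no truth frequencies for site {site!r}")
    q_alt = truth_freqs.alt_freqs(site).to_numpy()

    if mother_ids is None:
        candidates = [s for s in adults.sample_ids if s.startswith(site)] or adults.sample_ids
        if len(candidates) < design.n_mothers_per_site:
            raise ValueError(
                f"need {design.n_mothers_per_site} mothers, have {len(candidates)}"
            )
        mother_ids = candidates[: design.n_mothers_per_site]
    mother_ids = list(mother_ids)

    counts = design.progeny_counts()
    if len(mother_ids) != len(counts):
        raise ValueError("mother_ids length must match the design's line count")
    n_prog = sum(counts)
    s = np.asarray(selfing_rates, dtype=float)
    if s.ndim == 0:
        s = np.full(n_prog, float(s))
    if s.size != n_prog:
        raise ValueError(f"selfing_rates must be scalar or length {n_prog}, got {s.size}")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("selfing rates outside [0, 1]")

    mother_dos = adults.genotypes.loc[mother_ids].to_numpy(dtype=float)
    if np.isnan(mother_dos).all(axis=1).any():
        bad = [m for m, row in zip(mother_ids, mother_dos) if np.isnan(row).all()]
        raise ValueError(f"mothers with all-missing genotypes: {bad}")

    rows, ids, entries, truth = [], [], [], []
    k = 0
    for li, (mid, cnt) in enumerate(zip(mother_ids, counts)):
        line = f"{site}_ML{li + 1:02d}"
        for pj in range(cnt):
            selfed = bool(rng.random() < s[k])
            dos = simulate_progeny_dosages(
                mother_dos[li], q_alt, selfed, rng, noise.error_rate_epsilon
            )
            pid = f"{site}_{line.split('_')[-1]}_S{pj + 1:02d}"
            rows.append(dos)
            ids.append(pid)
            entries.append((species, site, line, mid, pid))
            truth.append((pid, mid, line, s[k], float(selfed)))
            k += 1

    prog = np.vstack(rows)
    # masking: per-call at the locus rate plus per-sample extra masking
    if noise.locus_missing_rate > 0:
        prog[rng.random(prog.shape) < noise.locus_missing_rate] = np.nan
    if noise.sample_missing_rate > 0:
        mask = rng.random(prog.shape) < noise.sample_missing_rate
        prog[mask] = np.nan

    all_dos = np.vstack([mother_dos, prog])
    matrix = GenotypeMatrix.from_arrays(
        all_dos, mother_ids + ids, adults.locus_ids, adults.locus_info.copy()
    )
    coords = getattr(adults, "site_coords", {}).get(site)
    fam = FamilyMap(
        pd.DataFrame(entries, columns=FamilyMap.REQUIRED),
        {site: coords} if coords else {},
    )
    truth_df = pd.DataFrame(
        truth, columns=["progeny_id", "mother_id", "line", "s_assigned", "selfed"]
    )
    return matrix, fam, truth_df


# ---------------------------------------------------------------------------
# DArT-style metadata
# ---------------------------------------------------------------------------

def inject_dart_metadata(
    matrix: GenotypeMatrix, noise: NoiseModel, seed: int
) -> GenotypeMatrix:
    """Attach per-locus reproducibility scores, clone ids and call rates.

    A fraction ``noise.fraction_multi_snp_clones`` of loci are paired onto
    shared clone ids (two SNPs per sequenced tag) so that one-SNP-per-clone
    thinning has work to do.
    """
    rng = np.random.default_rng(seed)
    m = matrix.copy()
    L = m.n_loci
    rep = np.clip(_draw_spec(rng, noise.reproducibility_distribution, L), 0.0, 1.0)

    clone_ids = np.array([f"C{j + 1:06d}" for j in range(L)], dtype=object)
    n_pairs = int(np.floor(noise.fraction_multi_snp_clones * L / 2))
    if n_pairs:
        chosen = rng.choice(L, size=2 * n_pairs, replace=False)
        for a, b in zip(chosen[:n_pairs], chosen[n_pairs:]):
            clone_ids[b] = clone_ids[a]

    m.locus_info["reproducibility"] = rep
    m.locus_info["clone_id"] = clone_ids
    m.locus_info["call_rate"] = (1.0 - m.locus_missing_rate()).to_numpy()
    return m
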