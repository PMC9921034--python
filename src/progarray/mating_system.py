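"""Per-progeny selfing-rate inference from mother-progeny SNP pairs.

Three estimators, all taking (mother dosages, progeny dosages, population
alternate-allele frequencies, per-allele genotyping error rate epsilon):

**MME** — a single-locus method-of-moments estimator in the Ritland moment
tradition.  At a locus where the mother is homozygous, observing the
non-maternal allele in the progeny is incompatible with selfing except via
genotyping error.  Writing X for that incompatibility indicator, d for its
probability under outcrossing and e for its probability under selfing (pure
error), E[X] = (1-s) d + s e, so summing over informative loci
(T = sum X, D = sum d, E = sum e) gives the linear moment solve

    s_hat = (D - T) / (D - E),  clamped to [0, 1].

Heterozygous-mother loci carry no signal for the indicator and drop out.

**ML** — a per-progeny maximum-likelihood estimator over the mixture
L(s) = prod_l [ s P(g_o | g_m, self, eps) + (1-s) P(g_o | g_m, outcross, q, eps) ],
maximised on a dense grid with local refinement.  Used as the independent
cross-check for the MME.

**CNN** — a simulation-trained 1-D convolutional network.  Progeny are
simulated from the site's observed mothers and allele frequencies with known
selfing status; the network regresses the realized selfing indicator from a
(loci x channels) image (mother dosage/2, progeny dosage/2, population
alternate-allele frequency, call mask), loci sorted by population minor-allele
frequency descending.  With a sigmoid head and squared-error loss the fitted
value approximates P(selfed | data); a deep ensemble (K independently seeded
members) supplies the point estimate (mean) and uncertainty (spread).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._nnet import ConvNet1D
from .genotype_io import GenotypeMatrix
from .popgen_stats import heterozygosity, isogenic_lines
from .synthetic_data import (
    AlleleFreqTable,
    FamilyDesign,
    LandscapeConfig,
    NoiseModel,
    generate_families,
    generate_landscape,
    simulate_progeny_dosages,
)

__all__ = [
    "SelfingEstimate",
    "MatingSimConfig",
    "CnnSpec",
    "locus_selfing_terms",
    "mme_selfing",
    "ml_selfing_oracle",
    "train_cnn",
    "predict_cnn",
    "CnnEnsemble",
    "flag_uninformative_sites",
    "compare_groups",
    "het_selfing_correlation",
    "recovery_experiment",
]


@dataclass
class SelfingEstimate:
    progeny_id: str
    method: str                      # "MME" | "CNN" | "ML"
    s_hat: float
    uncertainty: float
    n_informative_loci: int
    status: str = "ok"               # "ok" | "uninformative" | "impossible"

    def __post_init__(self) -> None:
        if self.status == "ok" and not 0.0 <= self.s_hat <= 1.0:
            raise ValueError(f"s_hat {self.s_hat} outside [0, 1]")


# ---------------------------------------------------------------------------
# Locus-level moment terms
# ---------------------------------------------------------------------------

def locus_selfing_terms(
    mother: np.ndarray,
    progeny: np.ndarray,
    q_alt: np.ndarray,
    epsilon: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (X, d, e) under the per-allele flip error model.

    X = 1 iff the progeny call carries the allele the homozygous mother could
    not have transmitted.  d = P(X=1 | outcross, mother call, pollen freq),
    e = P(X=1 | selfing) which is purely genotyping error.  Heterozygous
    mothers give X = d = e = 0 (uninformative).  Returns (X, d, e, informative)
    with missing or fixed-frequency loci excluded from ``informative``.
    """
    m = np.asarray(mother, dtype=float)
    o = np.asarray(progeny, dtype=float)
    q = np.asarray(q_alt, dtype=float)
    eps = float(epsilon)
    ok = ~np.isnan(m) & ~np.isnan(o) & (q > 0.0) & (q < 1.0)

    # P(observed call contains >=1 miscalled copy of the absent allele):
    err_hom = 2 * eps - eps * eps          # true homozygote looks non-homozygous
    det_het = 1.0 - eps * (1.0 - eps)      # true het retains the foreign allele

    X = np.zeros(m.shape)
    d = np.zeros(m.shape)
    e = np.zeros(m.shape)

    hom_ref = ok & (m == 0.0)
    X[hom_ref] = (o[hom_ref] >= 1.0).astype(float)
    d[hom_ref] = (1.0 - q[hom_ref]) * err_hom + q[hom_ref] * det_het
    e[hom_ref] = err_hom

    hom_alt = ok & (m == 2.0)
    X[hom_alt] = (o[hom_alt] <= 1.0).astype(float)
    d[hom_alt] = q[hom_alt] * err_hom + (1.0 - q[hom_alt]) * det_het
    e[hom_alt] = err_hom

    informative = (hom_ref | hom_alt) & (d > e)
    return X, d, e, informative


def mme_selfing(
    mother: np.ndarray,
    progeny: np.ndarray,
    q_alt: np.ndarray,
    epsilon: float,
    progeny_id: str = "",
) -> SelfingEstimate:
    """Moment estimate s_hat = (D - T) / (D - E) over informative loci."""
    X, d, e, inf = locus_selfing_terms(mother, progeny, q_alt, epsilon)
    n_inf = int(inf.sum())
    T, D, E = X[inf].sum(), d[inf].sum(), e[inf].sum()
    if n_inf == 0 or D - E <= 1e-12:
        return SelfingEstimate(progeny_id, "MME", np.nan, np.nan, n_inf,
                               status="uninformative")
    s = float(np.clip((D - T) / (D - E), 0.0, 1.0))
    m = (1.0 - s) * d[inf] + s * e[inf]
    var_T = float(np.sum(m * (1.0 - m)))
    se = float(np.sqrt(var_T) / (D - E))
    return SelfingEstimate(progeny_id, "MME", s, se, n_inf)


# ---------------------------------------------------------------------------
# Maximum-likelihood oracle
# ---------------------------------------------------------------------------

def _flip_matrix(eps: float) -> np.ndarray:
    """P(observed dosage | true dosage) under independent per-allele flips."""
    e = eps
    return np.array(
        [
            [(1 - e) ** 2, 2 * e * (1 - e), e ** 2],
            [e * (1 - e), e * e + (1 - e) ** 2, e * (1 - e)],
            [e ** 2, 2 * e * (1 - e), (1 - e) ** 2],
        ]
    )


def _true_genotype_probs(m: np.ndarray, q: np.ndarray, selfed: bool) -> np.ndarray:
    """(n_loci, 3) distribution of the true progeny dosage given mother dosage."""
    n = m.size
    out = np.zeros((n, 3))
    p = 1.0 - q
    if selfed:
        out[m == 0.0, 0] = 1.0
        out[m == 2.0, 2] = 1.0
        het = m == 1.0
        out[het] = [0.25, 0.5, 0.25]
    else:
        hr = m == 0.0
        out[hr, 0], out[hr, 1] = p[hr], q[hr]
        ha = m == 2.0
        ha_p = p[ha]
        out[ha, 1], out[ha, 2] = ha_p, 1.0 - ha_p
        het = m == 1.0
        out[het, 0] = 0.5 * p[het]
        out[het, 1] = 0.5
        out[het, 2] = 0.5 * q[het]
    return out


def ml_selfing_oracle(
    mother: np.ndarray,
    progeny: np.ndarray,
    q_alt: np.ndarray,
    epsilon: float,
    progeny_id: str = "",
    grid_step: float = 0.001,
) -> SelfingEstimate:
    """Grid + local-refinement maximiser of the per-progeny mixture likelihood."""
    m = np.asarray(mother, dtype=float)
    o = np.asarray(progeny, dtype=float)
    q = np.asarray(q_alt, dtype=float)
    ok = ~np.isnan(m) & ~np.isnan(o) & (q > 0.0) & (q < 1.0)
    if not ok.any():
        return SelfingEstimate(progeny_id, "ML", np.nan, np.nan, 0,
                               status="uninformative")
    m, o, q = m[ok], o[ok], q[ok]
    F = _flip_matrix(epsilon)
    oi = o.astype(int)
    pS = np.take_along_axis(
        _true_genotype_probs(m, q, True) @ F, oi[:, None], axis=1
    )[:, 0]
    pO = np.take_along_axis(
        _true_genotype_probs(m, q, False) @ F, oi[:, None], axis=1
    )[:, 0]
    if ((pS == 0) & (pO == 0)).any():
        return SelfingEstimate(progeny_id, "ML", np.nan, np.nan, int(ok.sum()),
                               status="impossible")
    diff = pS - pO
    n_inf = int(np.sum(np.abs(diff) > 1e-15))
    if n_inf == 0:
        return SelfingEstimate(progeny_id, "ML", np.nan, np.nan, 0,
                               status="uninformative")

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    with np.errstate(divide="ignore"):
        ll = np.log(np.maximum(pO[None, :] + grid[:, None] * diff[None, :], 1e-300))
    total = ll.sum(axis=1)
    best = int(np.argmax(total))
    lo = max(0.0, grid[best] - grid_step)
    hi = min(1.0, grid[best] + grid_step)

    def negll(s: float) -> float:
        return -float(np.sum(np.log(np.maximum(pO + s * diff, 1e-300))))

    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded")
    # bounded search never lands exactly on an endpoint; keep the grid point
    # when it is at least as good
    s_hat = min((float(res.x), float(grid[best])), key=negll)
    s_hat = float(np.clip(s_hat, 0.0, 1.0))
    # curvature-based standard error where the interior allows it
    h = 1e-4
    if h < s_hat < 1 - h:
        d2 = (negll(s_hat + h) - 2 * negll(s_hat) + negll(s_hat - h)) / h ** 2
        se = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
    else:
        se = np.nan
    return SelfingEstimate(progeny_id, "ML", s_hat, se, n_inf)


# ---------------------------------------------------------------------------
# CNN estimator
# ---------------------------------------------------------------------------

@dataclass
class MatingSimConfig:
    """Simulation settings for CNN training / validation progeny."""

    n_examples: int = 5000
    selfing_grid: Sequence[float] | None = None   # None -> s ~ Uniform(0, 1)
    epsilon: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selfing_grid is not None:
            g = np.asarray(self.selfing_grid, dtype=float)
            if ((g < 0) | (g > 1)).any():
                raise ValueError("selfing grid values outside [0, 1]")


@dataclass
class CnnSpec:
    """Architecture and training settings for the selfing CNN."""

    input_length: int = 2000
    conv_filters: tuple[int, int] = (16, 32)
    kernel: int = 7
    dense_units: int = 32
    ensemble_size: int = 5
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 3e-3
    validation_fraction: float = 0.1
    seed: int = 0


@dataclass
class CnnEnsemble:
    site: str
    spec: CnnSpec
    members: list[ConvNet1D]
    locus_order: np.ndarray          # indices into the training locus set
    q_alt: np.ndarray                # frequencies in matrix locus order
    validation_rmse: float = np.nan
    history: list[list[float]] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        arrays = {"locus_order": self.locus_order, "q_alt": self.q_alt}
        for i, mem in enumerate(self.members):
            for k, v in mem.state_dict().items():
                arrays[f"member{i}_{k}"] = v
        np.savez(
            path,
            site=np.array(self.site),
            n_members=np.array(len(self.members)),
            input_length=np.array(self.spec.input_length),
            validation_rmse=np.array(self.validation_rmse),
            **arrays,
        )

    @staticmethod
    def load(path: str | Path) -> "CnnEnsemble":
        z = np.load(path, allow_pickle=False)
        spec = CnnSpec(input_length=int(z["input_length"]))
        members = []
        for i in range(int(z["n_members"])):
            net = ConvNet1D(4, spec.input_length, spec.conv_filters, spec.kernel,
                            spec.dense_units, seed=i)
            net.load_state_dict({k.split("_", 1)[1]: z[k] for k in z.files
                                 if k.startswith(f"member{i}_")})
            members.append(net)
        return CnnEnsemble(str(z["site"]), spec, members, z["locus_order"],
                           z["q_alt"], float(z["validation_rmse"]))


def _maf_order(q_alt: np.ndarray, L: int) -> np.ndarray:
    """Indices of the L loci with highest population MAF, sorted descending."""
    maf = np.minimum(q_alt, 1.0 - q_alt)
    maf = np.where(np.isnan(maf), -1.0, maf)
    order = np.argsort(-maf, kind="stable")
    return order[: min(L, order.size)]


def _assemble_input(
    mother: np.ndarray, progeny: np.ndarray, q_alt: np.ndarray,
    order: np.ndarray, L: int
) -> np.ndarray:
    """(L, 4) network input: mother/2, progeny/2, alt freq, call mask.

    Shortfall relative to L is padded with zero rows carrying mask 0.
    """
    x = np.zeros((L, 4), np.float32)
    m = mother[order]
    o = progeny[order]
    q = q_alt[order]
    mask = (~np.isnan(m) & ~np.isnan(o)).astype(np.float32)
    n = order.size
    x[:n, 0] = np.where(np.isnan(m), 0.0, m) / 2.0
    x[:n, 1] = np.where(np.isnan(o), 0.0, o) / 2.0
    x[:n, 2] = np.where(np.isnan(q), 0.0, q)
    x[:n, 3] = mask
    x[:n, 0] *= mask
    x[:n, 1] *= mask
    return x


def train_cnn(
    mothers: GenotypeMatrix,
    freqs: AlleleFreqTable,
    site: str,
    sim: MatingSimConfig,
    spec: CnnSpec | None = None,
) -> CnnEnsemble:
    """Train a per-site deep ensemble on progeny simulated from the site's
    observed mothers and allele frequencies.

    Training selfing parameters are drawn from ``sim.selfing_grid`` (or
    Uniform(0,1)); each simulated progeny's regression label is its realized
    selfing indicator, so the squared-error-trained sigmoid output estimates
    the probability the progeny is selfed.
    """
    spec = spec or CnnSpec()
    rng = np.random.default_rng(sim.seed)
    q_alt = freqs.alt_freqs(site).reindex(mothers.locus_ids).to_numpy(dtype=float)
    mother_dos = mothers.dosages()
    L = spec.input_length
    order = _maf_order(q_alt, L)
    if order.size < L:
        import warnings

        warnings.warn(
            f"only {order.size} usable loci for input length {L}; padding", stacklevel=2
        )

    n = sim.n_examples
    X = np.zeros((n, L, 4), np.float32)
    y = np.zeros(n, np.float32)
    grid = None if sim.selfing_grid is None else np.asarray(sim.selfing_grid, float)
    for i in range(n):
        mi = int(rng.integers(0, mother_dos.shape[0]))
        s = float(rng.uniform()) if grid is None else float(rng.choice(grid))
        selfed = bool(rng.random() < s)
        prog = simulate_progeny_dosages(mother_dos[mi], q_alt, selfed, rng, sim.epsilon)
        X[i] = _assemble_input(mother_dos[mi], prog, q_alt, order, L)
        y[i] = float(selfed)

    n_val = max(1, int(round(spec.validation_fraction * n)))
    X_tr, y_tr = X[:-n_val], y[:-n_val]
    X_val, y_val = X[-n_val:], y[-n_val:]

    members, history = [], []
    for k in range(spec.ensemble_size):
        net = ConvNet1D(
            4, L, spec.conv_filters, spec.kernel, spec.dense_units,
            lr=spec.learning_rate, seed=spec.seed * 1000 + k,
        )
        hist = net.fit(X_tr, y_tr, epochs=spec.epochs, batch_size=spec.batch_size,
                       shuffle_seed=spec.seed * 1000 + k + 1)
        members.append(net)
        history.append(hist)

    preds = np.mean([m.predict(X_val) for m in members], axis=0)
    rmse = float(np.sqrt(np.mean((preds - y_val) ** 2)))
    return CnnEnsemble(site, spec, members, order, q_alt, rmse, history)


def predict_cnn(
    ensemble: CnnEnsemble,
    mother: np.ndarray,
    progeny: np.ndarray,
    site: str | None = None,
    progeny_id: str = "",
) -> SelfingEstimate:
    """Ensemble-mean selfing estimate with ensemble-spread uncertainty."""
    if site is not None and site != ensemble.site:
        raise ValueError(f"ensemble trained for site {ensemble.site!r}, got {site!r}")
    x = _assemble_input(
        np.asarray(mother, float), np.asarray(progeny, float),
        ensemble.q_alt, ensemble.locus_order, ensemble.spec.input_length,
    )[None, :, :]
    preds = np.array([m.predict(x)[0] for m in ensemble.members])
    return SelfingEstimate(
        progeny_id, "CNN", float(np.clip(preds.mean(), 0.0, 1.0)),
        float(preds.std()), int(ensemble.locus_order.size),
    )


def predict_cnn_batch(
    ensemble: CnnEnsemble,
    mothers: np.ndarray,
    progeny: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ensemble predictions for many mother/progeny dosage rows."""
    X = np.stack(
        [
            _assemble_input(m, o, ensemble.q_alt, ensemble.locus_order,
                            ensemble.spec.input_length)
            for m, o in zip(mothers, progeny)
        ]
    )
    all_preds = np.stack([m.predict(X) for m in ensemble.members])
    return all_preds.mean(axis=0), all_preds.std(axis=0)


# ---------------------------------------------------------------------------
# Site informativeness screen
# ---------------------------------------------------------------------------

def flag_uninformative_sites(
    mothers: GenotypeMatrix,
    site_mothers: dict[str, Sequence[str]],
    he_threshold: float = 0.01,
    identity_threshold: float = 0.99,
) -> pd.DataFrame:
    """Flag sites whose mothers carry too little variation for selfing inference.

    A site is flagged when mean mother expected heterozygosity falls below the
    threshold, or when every mother belongs to a single isogenic line.
    """
    rows = []
    for site, ids in site_mothers.items():
        he = heterozygosity(mothers, {site: list(ids)}).per_population.loc[site, "He"]
        groups = isogenic_lines(mothers, list(ids), identity_threshold)
        reason = []
        if he < he_threshold:
            reason.append(f"mother He {he:.4f} < {he_threshold}")
        if len(ids) > 1 and len(groups) == 1:
            reason.append("all mothers in a single isogenic line")
        rows.append(
            {
                "site": site,
                "flagged": bool(reason),
                "reason": "; ".join(reason),
                "mother_He": float(he),
                "n_isogenic_groups": len(groups),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------

def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U (normal approximation with tie correction)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {"U": float(u), "p_value": float(p), "n_a": a.size, "n_b": b.size}


def het_selfing_correlation(
    s_hat: Sequence[float], ho_difference: Sequence[float]
) -> dict:
    """Spearman rho between selfing estimates and progeny-minus-mother Ho."""
    s = np.asarray(s_hat, float)
    d = np.asarray(ho_difference, float)
    if s.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(s == s[0]) or np.all(d == d[0]):
        return {"rho": np.nan, "p_value": np.nan, "n": s.size,
                "note": "all values tied; rho undefined"}
    rho, p = stats.spearmanr(s, d)
    return {"rho": float(rho), "p_value": float(p), "n": int(s.size)}


# ---------------------------------------------------------------------------
# Simulation-based validation harness
# ---------------------------------------------------------------------------

def recovery_experiment(
    s_grid: Sequence[float],
    n_progeny_per_s: int,
    n_loci: int,
    epsilon: float,
    seed: int,
    methods: Sequence[str] = ("MME",),
    n_mothers: int = 10,
    inbreeding_f: float = 0.0,
    cnn_ensemble: "CnnEnsemble | None" = None,
    mothers: GenotypeMatrix | None = None,
    freqs: AlleleFreqTable | None = None,
) -> pd.DataFrame:
    """Simulate progeny across a selfing grid and run the requested estimators.

    One panmictic population supplies the mothers (MAF uniform on [0.1, 0.5])
    unless an existing mother panel + frequency table is given.  Returns one
    row per progeny with the true selfing parameter, the realized selfing
    indicator and one column per estimator.
    """
    if mothers is None or freqs is None:
        cfg = LandscapeConfig(
            n_populations=1, n_loci=n_loci, fst_target=0.0,
            inbreeding_f=inbreeding_f, n_adults_per_pop=n_mothers, seed=seed,
        )
        mothers, freqs, _ = generate_landscape(cfg)
    site = freqs.populations[0]
    q_alt = freqs.alt_freqs(site).reindex(mothers.locus_ids).to_numpy(dtype=float)
    mother_dos = mothers.dosages()

    rng = np.random.default_rng(seed + 1)
    rows = []
    prog_store, mom_store = [], []
    for s in s_grid:
        for rep in range(n_progeny_per_s):
            mi = int(rng.integers(0, mother_dos.shape[0]))
            selfed = bool(rng.random() < s)
            prog = simulate_progeny_dosages(mother_dos[mi], q_alt, selfed, rng, epsilon)
            row = {"s_true": float(s), "selfed": float(selfed), "mother_index": mi}
            if "MME" in methods:
                row["MME"] = mme_selfing(mother_dos[mi], prog, q_alt, epsilon).s_hat
            if "ML" in methods:
                row["ML"] = ml_selfing_oracle(mother_dos[mi], prog, q_alt, epsilon).s_hat
            prog_store.append(prog)
            mom_store.append(mother_dos[mi])
            rows.append(row)
    df = pd.DataFrame(rows)
    if "CNN" in methods:
        if cnn_ensemble is None:
            raise ValueError("CNN requested but no trained ensemble supplied")
        mean, _ = predict_cnn_batch(
            cnn_ensemble, np.stack(mom_store), np.stack(prog_store)
        )
        df["CNN"] = mean
    return df
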