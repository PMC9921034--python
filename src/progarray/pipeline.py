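"""End-to-end orchestration: simulate/load -> filter -> popgen -> mating -> resample.

The pipeline is a thin, deterministic driver over the library modules.  All
randomness flows from one global seed: stage s uses
``numpy.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[s],))`` so re-running
any stage from saved intermediates reproduces the end-to-end run.  Every
table written is regenerable from config + seed, and a provenance JSON
records both.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .genotype_io import (
    FamilyMap,
    FilterConfig,
    GenotypeMatrix,
    apply_filters,
    read_dart_csv,
    write_dart_csv,
)
from .mating_system import (
    CnnSpec,
    MatingSimConfig,
    compare_groups,
    flag_uninformative_sites,
    het_selfing_correlation,
    ml_selfing_oracle,
    mme_selfing,
    predict_cnn_batch,
    train_cnn,
)
from .popgen_stats import (
    fis,
    isolation_by_distance,
    kinship_mom,
    pairwise_fst,
)
from .seed_sampling import (
    AmongSiteScheme,
    WithinSiteScheme,
    among_site_resample,
    within_site_resample,
)
from .synthetic_data import (
    AlleleFreqTable,
    FamilyDesign,
    LandscapeConfig,
    NoiseModel,
    generate_families,
    generate_landscape,
    inject_dart_metadata,
)

logger = logging.getLogger(__name__)

STAGE_KEYS = {"simulate": 1, "filter": 2, "popgen": 3, "mating": 4, "resample": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    """Named substream seed below 2**31, derived from the global seed."""
    ss = np.random.SeedSequence(global_seed, spawn_key=(STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full run configuration.

    Exactly one of ``input_csv`` (+ optional ``family_map``) or ``scenario``
    must be given.  ``scenario`` is a mapping understood by
    :func:`simulate_scenario`.
    """

    out_dir: str = "progarray_out"
    seed: int = 0
    input_csv: str | None = None
    family_map: str | None = None
    scenario: Mapping[str, Any] | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    epsilon: float = 0.005
    run_ml: bool = True
    cnn_enabled: bool = False
    cnn_spec: CnnSpec = field(default_factory=CnnSpec)
    cnn_n_train: int = 2000
    within_scheme: WithinSiteScheme = field(default_factory=WithinSiteScheme)
    among_scheme: AmongSiteScheme = field(default_factory=AmongSiteScheme)
    germination: Mapping[str, tuple[int, int]] | None = None  # species -> (ok, total)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.input_csv is None):
            raise ValueError("exactly one input source (input_csv | scenario) required")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "filters" in kwargs:
            kwargs["filters"] = FilterConfig(**kwargs["filters"])
        if "cnn_spec" in kwargs:
            kwargs["cnn_spec"] = CnnSpec(**kwargs["cnn_spec"])
        if "within_scheme" in kwargs:
            kwargs["within_scheme"] = WithinSiteScheme(**kwargs["within_scheme"])
        if "among_scheme" in kwargs:
            sch = kwargs["among_scheme"]
            if "maf_thresholds" in sch:
                sch["maf_thresholds"] = tuple(sch["maf_thresholds"])
            kwargs["among_scheme"] = AmongSiteScheme(**sch)
        return RunConfig(**kwargs)


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.6g")
        (out / "summary.json").write_text(
            json.dumps(self.scalars, indent=2, default=float)
        )
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )


# ---------------------------------------------------------------------------
# Scenario simulation
# ---------------------------------------------------------------------------

def simulate_scenario(
    scenario: Mapping[str, Any], seed: int
) -> tuple[GenotypeMatrix, FamilyMap, pd.DataFrame, dict[str, list[str]]]:
    """Simulate a landscape plus per-site progeny arrays from a scenario dict.

    Recognised keys (all optional): ``species`` label, ``n_sites``, ``n_loci``,
    ``fst_target``, ``inbreeding_f``, ``n_adults_per_pop``, ``selfing`` (scalar
    or per-site list), ``epsilon``, ``locus_missing_rate``,
    ``fraction_multi_snp_clones``, ``design`` (FamilyDesign kwargs).
    """
    sc = dict(scenario)
    design = FamilyDesign(**sc.get("design", {}))
    n_sites = int(sc.get("n_sites", 4))
    n_adults = max(int(sc.get("n_adults_per_pop", design.n_mothers_per_site)),
                   design.n_mothers_per_site)
    cfg = LandscapeConfig(
        n_populations=n_sites,
        n_loci=int(sc.get("n_loci", 2000)),
        fst_target=float(sc.get("fst_target", 0.3)),
        inbreeding_f=sc.get("inbreeding_f", 0.0),
        n_adults_per_pop=n_adults,
        maf_distribution=tuple(sc.get("maf_distribution", ("uniform", 0.1, 0.5))),
        seed=seed,
    )
    adults, freqs, pops = generate_landscape(cfg)
    noise = NoiseModel(
        error_rate_epsilon=float(sc.get("epsilon", 0.005)),
        locus_missing_rate=float(sc.get("locus_missing_rate", 0.05)),
        reproducibility_distribution=tuple(
            sc.get("reproducibility_distribution", ("point", 1.0))
        ),
        fraction_multi_snp_clones=float(sc.get("fraction_multi_snp_clones", 0.0)),
    )
    selfing = sc.get("selfing", 0.3)
    site_s = (
        list(np.broadcast_to(np.asarray(selfing, dtype=float), (n_sites,)))
        if np.ndim(selfing) <= 1
        else list(selfing)
    )
    species = str(sc.get("species", "SpA"))

    frames, fams, truths = [], [], []
    for i, site in enumerate(freqs.populations):
        fam_matrix, fam_map, truth = generate_families(
            adults, design, site_s[i], freqs, noise, seed + 101 + i,
            site=site, species=species,
        )
        frames.append(fam_matrix)
        fams.append(fam_map)
        truths.append(truth)

    genotypes = pd.concat([f.genotypes for f in frames])
    genotypes = genotypes[~genotypes.index.duplicated()]
    combined = GenotypeMatrix(genotypes, adults.locus_info.copy())
    combined = inject_dart_metadata(combined, noise, seed + 7)
    coords = getattr(adults, "site_coords", {})
    fam = FamilyMap(
        pd.concat([f.entries for f in fams], ignore_index=True),
        {s: coords[s] for s in coords},
    )
    truth = pd.concat(truths, ignore_index=True)
    site_mothers = {s: fam.mothers_for_site(s) for s in fam.sites}
    return combined, fam, truth, site_mothers


# ---------------------------------------------------------------------------
# Statistical helper exposed as its own operation
# ---------------------------------------------------------------------------

def compare_proportions(
    successes_a: int, n_a: int, successes_b: int, n_b: int
) -> dict:
    """Two-sided two-proportion chi-square test with continuity correction."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("zero denominator")
    table = np.array(
        [[successes_a, n_a - successes_a], [successes_b, n_b - successes_b]]
    )
    res = stats.chi2_contingency(table, correction=True)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "prop_a": successes_a / n_a,
        "prop_b": successes_b / n_b,
        "method": "chi-square with continuity correction",
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run all feasible stages in dependency order and write the report."""
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    bundle = ReportBundle()
    bundle.provenance = {
        "package": "progarray",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_KEYS},
    }

    # -- input ----------------------------------------------------------
    truth = None
    try:
        if config.scenario is not None:
            matrix, fam, truth, site_mothers = simulate_scenario(
                config.scenario, stage_seed(config.seed, "simulate")
            )
            bundle.tables["truth_selfing"] = truth
        else:
            matrix = read_dart_csv(config.input_csv)
            fam = FamilyMap.from_tsv(config.family_map) if config.family_map else None
            site_mothers = (
                {s: fam.mothers_for_site(s) for s in fam.sites} if fam else None
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", exc) from exc

    # -- filter -----------------------------------------------------------
    try:
        matrix, report = apply_filters(matrix, config.filters)
        bundle.provenance["filter_report"] = {
            "loci_removed": report.loci_removed,
            "samples_removed": report.samples_removed,
            "order": list(report.order),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("filter", exc) from exc

    if fam is not None:
        keep = set(matrix.sample_ids)
        fam = FamilyMap(
            fam.entries[
                fam.entries["mother_id"].isin(keep)
                & fam.entries["progeny_id"].isin(keep)
            ].reset_index(drop=True),
            fam.site_coords,
        )
        site_mothers = {s: fam.mothers_for_site(s) for s in fam.sites}

    # -- popgen -----------------------------------------------------------
    try:
        if fam is not None:
            populations = {s: site_mothers[s] for s in fam.sites if site_mothers[s]}
        else:
            prefixes = pd.Series(matrix.sample_ids).str.split("_").str[0]
            populations = {
                p: [s for s, pre in zip(matrix.sample_ids, prefixes) if pre == p]
                for p in sorted(prefixes.unique())
            }
        div = fis(matrix, populations)
        bundle.tables["diversity"] = div.per_population.reset_index(names="population")
        multi = {p: v for p, v in populations.items() if len(v) >= 2}
        if len(multi) >= 2:
            coords = fam.site_coords if fam is not None else {}
            fst_res = pairwise_fst(
                matrix, multi, coords if len(coords) == len(multi) else None
            )
            bundle.tables["fst_pairs"] = fst_res.per_pair
            if "distance_km" in fst_res.per_pair.columns and len(fst_res.per_pair) >= 3:
                bundle.scalars["isolation_by_distance"] = isolation_by_distance(fst_res)
        freqs = AlleleFreqTable.from_matrix(matrix, populations)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("popgen", exc) from exc

    # -- mating system ----------------------------------------------------
    if fam is not None and len(fam.entries):
        try:
            flags = flag_uninformative_sites(matrix, site_mothers)
            bundle.tables["site_flags"] = flags
            flagged = set(flags.loc[flags["flagged"], "site"])
            est_rows, kin_rows = [], []
            mseed = stage_seed(config.seed, "mating")
            for site in fam.sites:
                q_alt = freqs.alt_freqs(site).reindex(matrix.locus_ids).to_numpy(float)
                ensemble = None
                if config.cnn_enabled and site not in flagged:
                    mothers = matrix.subset(samples=site_mothers[site])
                    ensemble = train_cnn(
                        mothers, freqs, site,
                        MatingSimConfig(n_examples=config.cnn_n_train,
                                        epsilon=config.epsilon, seed=mseed),
                        config.cnn_spec,
                    )
                sub = fam.entries[fam.entries["site"] == site]
                moms, progs, meta = [], [], []
                for _, row in sub.iterrows():
                    mdos = matrix.genotypes.loc[row["mother_id"]].to_numpy(float)
                    pdos = matrix.genotypes.loc[row["progeny_id"]].to_numpy(float)
                    moms.append(mdos)
                    progs.append(pdos)
                    meta.append(row)
                    for method, fn in (
                        ("MME", mme_selfing),
                        *((("ML", ml_selfing_oracle),) if config.run_ml else ()),
                    ):
                        est = fn(mdos, pdos, q_alt, config.epsilon,
                                 progeny_id=row["progeny_id"])
                        est_rows.append(
                            {"progeny_id": row["progeny_id"], "site": site,
                             "line": row["line"], "species": row["species"],
                             "method": method, "s_hat": est.s_hat,
                             "uncertainty": est.uncertainty,
                             "n_informative_loci": est.n_informative_loci,
                             "status": est.status,
                             "excluded": site in flagged}
                        )
                    kin = kinship_mom(
                        matrix, freqs, [(row["mother_id"], row["progeny_id"])], site
                    ).per_pair.iloc[0]
                    kin_rows.append(
                        {"site": site, "mother_id": row["mother_id"],
                         "progeny_id": row["progeny_id"],
                         "kinship": kin["kinship"], "n_loci": kin["n_loci"]}
                    )
                if ensemble is not None and moms:
                    mean, spread = predict_cnn_batch(
                        ensemble, np.stack(moms), np.stack(progs)
                    )
                    for row, mu, sd in zip(meta, mean, spread):
                        est_rows.append(
                            {"progeny_id": row["progeny_id"], "site": site,
                             "line": row["line"], "species": row["species"],
                             "method": "CNN", "s_hat": float(mu),
                             "uncertainty": float(sd),
                             "n_informative_loci": int(ensemble.locus_order.size),
                             "status": "ok", "excluded": site in flagged}
                        )
            est = pd.DataFrame(est_rows)
            bundle.tables["selfing_estimates"] = est
            bundle.tables["kinship"] = pd.DataFrame(kin_rows)

            usable = est[(~est["excluded"]) & (est["status"] == "ok")]
            species_list = sorted(usable["species"].unique())
            if len(species_list) == 2:
                a, b = species_list
                for method in sorted(usable["method"].unique()):
                    va = usable[(usable.species == a) & (usable.method == method)]["s_hat"]
                    vb = usable[(usable.species == b) & (usable.method == method)]["s_hat"]
                    if len(va) and len(vb):
                        bundle.scalars[f"mannwhitney_{method}"] = compare_groups(va, vb)
            # selfing vs heterozygosity-difference correlation
            mme_est = usable[usable["method"] == "MME"].set_index("progeny_id")
            if len(mme_est) >= 3:
                dos = matrix.genotypes
                ho = lambda sid: float(np.nanmean(dos.loc[sid].to_numpy(float) == 1.0))
                pairs = fam.entries.set_index("progeny_id")
                shared = [p for p in mme_est.index if p in pairs.index]
                diffs = [ho(p) - ho(pairs.loc[p, "mother_id"]) for p in shared]
                bundle.scalars["het_selfing_spearman"] = het_selfing_correlation(
                    mme_est.loc[shared, "s_hat"].to_numpy(), diffs
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("mating", exc) from exc
    else:
        logger.info("no family map: mating-system stage skipped")

    # -- resampling -------------------------------------------------------
    if fam is not None and len(fam.entries):
        try:
            rseed = stage_seed(config.seed, "resample")
            wscheme = WithinSiteScheme(
                splits=config.within_scheme.splits,
                n_replicates=config.within_scheme.n_replicates, seed=rseed,
            )
            bundle.tables["within_site_distances"] = within_site_resample(
                matrix, fam, wscheme
            )
            mothers_panel = matrix.subset(
                samples=[m for s in fam.sites for m in site_mothers[s]]
            )
            ascheme = AmongSiteScheme(
                n_sites_range=config.among_scheme.n_sites_range,
                lines_per_site=config.among_scheme.lines_per_site,
                n_replicates=config.among_scheme.n_replicates,
                maf_thresholds=config.among_scheme.maf_thresholds,
                seed=rseed + 1,
            )
            bundle.tables["allele_capture"] = among_site_resample(
                matrix, fam, mothers_panel, ascheme
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("resample", exc) from exc
    else:
        logger.info("no family map: resampling stage skipped")

    # -- extra comparisons ------------------------------------------------
    if config.germination:
        items = list(config.germination.items())
        if len(items) == 2:
            (sa, (ga, na)), (sb, (gb, nb)) = items
            res = compare_proportions(ga, na, gb, nb)
            res["species"] = [sa, sb]
            bundle.scalars["germination_comparison"] = res

    bundle.provenance["runtime_s"] = round(time.time() - t0, 2)
    bundle.write(config.out_dir)
    # persist filtered matrix + family map for stage re-runs
    write_dart_csv(matrix, Path(config.out_dir) / "filtered_genotypes.csv")
    if fam is not None:
        fam.to_tsv(Path(config.out_dir) / "family_map.tsv")
    return bundle
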