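"""Genotype matrices, family maps, DArT-style CSV / VCF round-tripping and QC filters.

The central container is :class:`GenotypeMatrix`: a samples x loci table of
alternate-allele dosages (0, 1, 2, NaN for missing) plus per-locus metadata
(clone/tag id, reproducibility score, call rate) of the kind shipped with
reduced-representation genotyping reports such as DArTseq.  Quality control
follows the conventional recipe for such data: drop low-reproducibility
markers, drop high-missingness markers, thin to one SNP per sequenced tag
("clone"), then drop high-missingness samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_SYMBOLS = {"-", "", "NA", "NaN", "nan"}

#: metadata columns carried for every locus
LOCUS_COLUMNS = ["clone_id", "ref", "alt", "reproducibility", "call_rate"]


class GenotypeMatrixError(ValueError):
    """Raised for malformed genotype inputs."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci, alternate-allele dosage in {0, 1, 2, NaN}.

    Attributes
    ----------
    genotypes
        DataFrame indexed by sample id, columns are locus ids, values are
        float dosages with NaN marking missing calls.
    locus_info
        DataFrame indexed by locus id with columns ``clone_id``, ``ref``,
        ``alt``, ``reproducibility``, ``call_rate`` (any may be NaN until
        metadata is attached).
    """

    genotypes: pd.DataFrame
    locus_info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genotypes.index.duplicated().any():
            dupes = self.genotypes.index[self.genotypes.index.duplicated()].tolist()
            raise GenotypeMatrixError(f"duplicate sample ids: {dupes}")
        if not self.genotypes.columns.equals(self.locus_info.index):
            self.locus_info = self.locus_info.reindex(self.genotypes.columns)
        vals = self.genotypes.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeMatrixError(
                f"invalid dosage {vals[i, j]!r} at sample "
                f"{self.genotypes.index[i]!r}, locus {self.genotypes.columns[j]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def dosages(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Dosage array (samples x loci) as float with NaN for missing."""
        df = self.genotypes if samples is None else self.genotypes.loc[list(samples)]
        return df.to_numpy(dtype=float)

    def sample_missing_rate(self) -> pd.Series:
        return self.genotypes.isna().mean(axis=1)

    def locus_missing_rate(self) -> pd.Series:
        return self.genotypes.isna().mean(axis=0)

    def subset(
        self,
        samples: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        g = self.genotypes
        if samples is not None:
            g = g.loc[list(samples)]
        if loci is not None:
            g = g[list(loci)]
        return GenotypeMatrix(g.copy(), self.locus_info.loc[g.columns].copy())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.genotypes.copy(), self.locus_info.copy())

    @staticmethod
    def from_arrays(
        dosages: np.ndarray,
        sample_ids: Sequence[str],
        locus_ids: Sequence[str],
        locus_info: pd.DataFrame | None = None,
    ) -> "GenotypeMatrix":
        g = pd.DataFrame(np.asarray(dosages, dtype=float), index=list(sample_ids),
                         columns=list(locus_ids))
        if locus_info is None:
            locus_info = pd.DataFrame(
                {
                    "clone_id": list(locus_ids),
                    "ref": "A",
                    "alt": "T",
                    "reproducibility": np.nan,
                    "call_rate": np.nan,
                },
                index=list(locus_ids),
            )
        return GenotypeMatrix(g, locus_info)


@dataclass
class FamilyMap:
    """Hierarchical sampling design: species -> site -> maternal line.

    ``entries`` has one row per progeny with columns
    ``species, site, line, mother_id, progeny_id``; ``site_coords`` maps a
    site code to (lon, lat) in decimal degrees (WGS84 assumed).
    """

    entries: pd.DataFrame
    site_coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    REQUIRED = ["species", "site", "line", "mother_id", "progeny_id"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.entries.columns]
        if missing:
            raise GenotypeMatrixError(f"family map missing columns: {missing}")
        dup = self.entries["progeny_id"].duplicated()
        if dup.any():
            raise GenotypeMatrixError(
                "progeny ids assigned to more than one maternal line: "
                f"{self.entries.loc[dup, 'progeny_id'].tolist()}"
            )

    @property
    def sites(self) -> list[str]:
        return sorted(self.entries["site"].unique())

    def lines_for_site(self, site: str) -> dict[str, list[str]]:
        """mother_id -> list of progeny ids for one site."""
        sub = self.entries[self.entries["site"] == site]
        return {m: g["progeny_id"].tolist() for m, g in sub.groupby("mother_id", sort=True)}

    def mothers_for_site(self, site: str) -> list[str]:
        sub = self.entries[self.entries["site"] == site]
        return sorted(sub["mother_id"].unique())

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        ids = set(matrix.sample_ids)
        referenced = set(self.entries["mother_id"]) | set(self.entries["progeny_id"])
        absent = sorted(referenced - ids)
        if absent:
            raise GenotypeMatrixError(f"family map references unknown samples: {absent[:5]}")

    def to_tsv(self, path: str | Path) -> None:
        df = self.entries.copy()
        df["lon"] = df["site"].map(lambda s: self.site_coords.get(s, (np.nan, np.nan))[0])
        df["lat"] = df["site"].map(lambda s: self.site_coords.get(s, (np.nan, np.nan))[1])
        df.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path) -> "FamilyMap":
        df = pd.read_csv(path, sep="\t", dtype={"site": str, "line": str})
        coords = {}
        if {"lon", "lat"}.issubset(df.columns):
            for site, g in df.groupby("site"):
                coords[site] = (float(g["lon"].iloc[0]), float(g["lat"].iloc[0]))
            df = df.drop(columns=["lon", "lat"])
        return FamilyMap(df, coords)


# ---------------------------------------------------------------------------
# DArT-style CSV
# ---------------------------------------------------------------------------

def read_dart_csv(path: str | Path) -> GenotypeMatrix:
    """Read a one-row-per-locus DArT-style dosage CSV.

    Expected columns: ``LocusID, CloneID, Ref, Alt, RepAvg, CallRate`` then one
    column per sample holding alternate-allele dosage 0/1/2 with ``-``, empty
    or ``NA`` for missing.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta_cols = ["LocusID", "CloneID", "Ref", "Alt", "RepAvg", "CallRate"]
    missing_meta = [c for c in meta_cols if c not in raw.columns]
    if missing_meta:
        raise GenotypeMatrixError(f"missing metadata columns: {missing_meta}")
    sample_cols = [c for c in raw.columns if c not in meta_cols]
    if len(set(sample_cols)) != len(sample_cols):
        raise GenotypeMatrixError("duplicate sample id column in header")

    dosages = np.full((len(sample_cols), len(raw)), np.nan)
    for j, (_, row) in enumerate(raw.iterrows()):
        for i, s in enumerate(sample_cols):
            tok = row[s].strip()
            if tok in MISSING_SYMBOLS:
                continue
            if tok not in {"0", "1", "2"}:
                raise GenotypeMatrixError(
                    f"malformed dosage {tok!r} at locus row {j + 1}, sample column {s!r}"
                )
            dosages[i, j] = float(tok)

    locus_info = pd.DataFrame(
        {
            "clone_id": raw["CloneID"].to_numpy(),
            "ref": raw["Ref"].to_numpy(),
            "alt": raw["Alt"].to_numpy(),
            "reproducibility": pd.to_numeric(raw["RepAvg"], errors="coerce").to_numpy(),
            "call_rate": pd.to_numeric(raw["CallRate"], errors="coerce").to_numpy(),
        },
        index=raw["LocusID"].to_numpy(),
    )
    if locus_info.index.duplicated().any():
        raise GenotypeMatrixError("duplicate locus ids in file")
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=sample_cols, columns=locus_info.index), locus_info
    )


def write_dart_csv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Inverse of :func:`read_dart_csv` (lossless dosage round-trip)."""
    li = matrix.locus_info
    out = pd.DataFrame(
        {
            "LocusID": li.index,
            "CloneID": li["clone_id"].to_numpy(),
            "Ref": li["ref"].to_numpy(),
            "Alt": li["alt"].to_numpy(),
            "RepAvg": li["reproducibility"].to_numpy(),
            "CallRate": li["call_rate"].to_numpy(),
        }
    )
    dos = matrix.genotypes.to_numpy(dtype=float).T  # loci x samples
    cols = {
        s: ["-" if np.isnan(v) else str(int(v)) for v in dos[:, i]]
        for i, s in enumerate(matrix.sample_ids)
    }
    out = pd.concat([out, pd.DataFrame(cols)], axis=1)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """SNP/sample QC thresholds.

    Defaults: markers below 98% reproducibility or above 10% missing calls
    are dropped, multi-SNP sequence tags are thinned to one SNP, and samples
    missing more than 40% of calls are excluded.
    """

    min_reproducibility: float = 0.98
    max_locus_missing: float = 0.10
    one_snp_per_clone: bool = True
    max_sample_missing: float = 0.40
    #: rule application order; locus-level rules precede the sample rule so
    #: that sample missingness is measured on the retained loci
    order: tuple[str, ...] = (
        "reproducibility",
        "locus_missing",
        "clone_thinning",
        "sample_missing",
    )

    def __post_init__(self) -> None:
        for name in ("min_reproducibility", "max_locus_missing", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenotypeMatrixError(f"{name}={v} outside [0, 1]")


@dataclass
class FilterReport:
    loci_removed: dict[str, int] = field(default_factory=dict)
    samples_removed: dict[str, int] = field(default_factory=dict)
    order: tuple[str, ...] = ()
    n_loci_in: int = 0
    n_loci_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def apply_filters(
    matrix: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the QC rules of ``cfg`` in ``cfg.order`` and report removals."""
    cfg = cfg or FilterConfig()
    m = matrix.copy()
    report = FilterReport(
        order=cfg.order,
        n_loci_in=m.n_loci,
        n_samples_in=m.n_samples,
    )
    for rule in cfg.order:
        if rule == "reproducibility":
            rep = m.locus_info["reproducibility"]
            keep = rep.isna() | (rep >= cfg.min_reproducibility)
            report.loci_removed[rule] = int((~keep).sum())
            m = m.subset(loci=m.locus_info.index[keep])
        elif rule == "locus_missing":
            keep = m.locus_missing_rate() <= cfg.max_locus_missing
            report.loci_removed[rule] = int((~keep).sum())
            m = m.subset(loci=m.genotypes.columns[keep])
        elif rule == "clone_thinning":
            if not cfg.one_snp_per_clone:
                report.loci_removed[rule] = 0
                continue
            li = m.locus_info.copy()
            li["_call_rate_obs"] = 1.0 - m.locus_missing_rate()
            # keep the SNP with the highest observed call rate; tie -> lowest locus id
            li = li.sort_values(["_call_rate_obs"], ascending=False, kind="stable")
            li["_locus"] = li.index
            li = li.sort_values(["clone_id", "_call_rate_obs", "_locus"],
                                ascending=[True, False, True], kind="stable")
            keep_ids = li.drop_duplicates("clone_id", keep="first")["_locus"]
            keep_ids = [l for l in m.locus_ids if l in set(keep_ids)]
            report.loci_removed[rule] = m.n_loci - len(keep_ids)
            m = m.subset(loci=keep_ids)
        elif rule == "sample_missing":
            keep = m.sample_missing_rate() <= cfg.max_sample_missing
            report.samples_removed[rule] = int((~keep).sum())
            m = m.subset(samples=m.genotypes.index[keep])
        else:
            raise GenotypeMatrixError(f"unknown filter rule {rule!r}")
        if m.n_loci == 0:
            raise GenotypeMatrixError(f"empty matrix: all loci removed at rule {rule!r}")
    report.n_loci_out = m.n_loci
    report.n_samples_out = m.n_samples
    return m, report


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def export_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2 with all loci on an unplaced contig."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=unplaced>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids),
    ]
    dos = matrix.genotypes.to_numpy(dtype=float)
    for j, locus in enumerate(matrix.locus_ids):
        info = matrix.locus_info.loc[locus]
        ref = str(info["ref"]) if pd.notna(info["ref"]) else "A"
        alt = str(info["alt"]) if pd.notna(info["alt"]) else "T"
        gts = "\t".join(
            "./." if np.isnan(dos[i, j]) else _GT[dos[i, j]]
            for i in range(matrix.n_samples)
        )
        lines.append(f"unplaced\t{j + 1}\t{locus}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")
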