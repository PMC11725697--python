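"""Tabular data contracts: detection matrices, covariates, masks, and file I/O.

Files are plain CSV, 1-based in site and occasion (field convention);
in-memory arrays are 0-based.  Masked (unsampled) site-by-occasion cells
are stored as absent rows on disk and as ``-1`` sentinels in memory; they
contribute nothing to any likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError, ModelGraph, StudyDesign

__all__ = ["DataError", "DetectionData", "read_detection_csv", "read_dataset", "write_dataset"]


class DataError(ValueError):
    """Raised when input tables violate the data contract."""


@dataclass
class DetectionData:
    """Detection/non-detection histories for every species in a study.

    ``y[species]`` is an (I, J) integer matrix of counts in ``[0, K]``
    (binary for occupancy-state species), with ``-1`` at masked cells.
    ``covariates`` is a site-level table (one row per site-row of the
    design) whose columns are referenced by name from model formulas.
    """

    design: StudyDesign
    y: dict
    covariates: pd.DataFrame = None
    site_ids: list = None

    def __post_init__(self):
        I, J = self.design.n_sites, self.design.n_occasions
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(I))
        if len(self.covariates) != I:
            raise DataError(
                f"covariates has {len(self.covariates)} rows, design has {I} sites"
            )
        if self.site_ids is None:
            self.site_ids = list(range(1, I + 1))
        mask = self.design.observed_mask
        for sp, m in self.y.items():
            m = np.asarray(m, dtype=np.int64)
            if m.shape != (I, J):
                raise DataError(f"y[{sp!r}] shape {m.shape} != ({I}, {J})")
            if (m[mask] < 0).any():
                raise DataError(f"negative count in y[{sp!r}] at an observed cell")
            if (m[mask] > self.design.n_subsamples).any():
                raise DataError(
                    f"y[{sp!r}] exceeds K={self.design.n_subsamples} at an observed cell"
                )
            m = m.copy()
            m[~mask] = -1
            self.y[sp] = m

    @property
    def species(self) -> list:
        return list(self.y)

    def ever_detected(self, species: str) -> np.ndarray:
        """Per site: was the species detected on any sampled occasion?"""
        m = self.y[species]
        return ((m > 0) & self.design.observed_mask).any(axis=1)

    def sufficient_stats(self, species: str, binary: bool = False):
        """Per-site (sum of y, sum of trials) over sampled occasions.

        With site-level detection probability the within-site occasions are
        exchangeable binomial draws, so these totals carry the entire
        observation likelihood.  ``binary`` clips counts to 0/1 (occupancy
        observation model, one Bernoulli trial per occasion).
        """
        mask = self.design.observed_mask
        m = np.where(mask, self.y[species], 0)
        if binary:
            m = np.minimum(m, 1)
            trials = mask.sum(axis=1).astype(float)
        else:
            trials = mask.sum(axis=1) * float(self.design.n_subsamples)
        return m.sum(axis=1).astype(float), trials

    def covariate_row(self, i: int) -> dict:
        """Covariates for site-row ``i``, including year dummies."""
        row = {k: float(v) for k, v in self.covariates.iloc[i].items()}
        if self.design.year_index is not None:
            years = self.design.years
            for k, yv in enumerate(years[1:], start=1):
                row[f"year{k}"] = 1.0 if self.design.year_index[i] == yv else 0.0
        return row

    def design_matrix(self, params) -> np.ndarray:
        """Columns of the (I, P) design matrix for a list of intercept /
        year / covariate ParamSpecs (gamma entries are excluded)."""
        I = self.design.n_sites
        cols = []
        for p in params:
            if p.kind == "intercept":
                cols.append(np.ones(I))
            elif p.kind in ("year", "covariate"):
                if p.kind == "covariate" and p.covariate not in self.covariates.columns:
                    raise ConfigurationError(f"missing covariate column {p.covariate!r}")
                if p.kind == "year":
                    years = self.design.years
                    k = int(p.covariate.removeprefix("year"))
                    cols.append((self.design.year_index == years[k]).astype(float))
                else:
                    cols.append(self.covariates[p.covariate].to_numpy(dtype=float))
            else:
                continue
        return np.column_stack(cols) if cols else np.ones((I, 0))


def read_detection_csv(path, design: StudyDesign) -> np.ndarray:
    """Read one species' long-format detections (site, occasion, y, K).

    Rows absent from the file are masked cells; ``y > K`` or duplicated
    (site, occasion) keys raise DataError with the offending row.
    """
    df = pd.read_csv(path)
    required = {"site", "occasion", "y", "K"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    dup = df.duplicated(subset=["site", "occasion"])
    if dup.any():
        raise DataError(f"{path}: duplicate (site, occasion) at row {int(df.index[dup][0])}")
    bad = df["y"] > df["K"]
    if bad.any():
        r = df[bad].iloc[0]
        raise DataError(
            f"{path}: y={int(r['y'])} exceeds K={int(r['K'])} at site {int(r['site'])}, "
            f"occasion {int(r['occasion'])}"
        )
    I, J = design.n_sites, design.n_occasions
    y = np.full((I, J), -1, dtype=np.int64)
    si = df["site"].to_numpy(int) - 1
    oj = df["occasion"].to_numpy(int) - 1
    if (si < 0).any() or (si >= I).any() or (oj < 0).any() or (oj >= J).any():
        raise DataError(f"{path}: site/occasion index outside the study design")
    y[si, oj] = df["y"].to_numpy(int)
    return y


def write_dataset(data: DetectionData, out_dir, truth: dict | None = None) -> None:
    """Write detections_<species>.csv, covariates.csv, mask.csv (+truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = data.design
    mask = d.observed_mask
    si, oj = np.nonzero(mask)
    for sp, m in data.y.items():
        pd.DataFrame(
            {
                "site": si + 1,
                "occasion": oj + 1,
                "y": m[si, oj],
                "K": d.n_subsamples,
            }
        ).to_csv(out / f"detections_{sp}.csv", index=False)
    long = data.covariates.copy()
    long.insert(0, "site", np.arange(1, d.n_sites + 1))
    long.melt(id_vars="site", var_name="name", value_name="value").to_csv(
        out / "covariates.csv", index=False, float_format="%.17g"
    )
    ii, jj = np.meshgrid(np.arange(d.n_sites), np.arange(d.n_occasions), indexing="ij")
    pd.DataFrame(
        {"site": ii.ravel() + 1, "occasion": jj.ravel() + 1, "observed": mask.ravel().astype(int)}
    ).to_csv(out / "mask.csv", index=False)
    meta = {
        "n_sites": d.n_sites,
        "n_occasions": d.n_occasions,
        "n_subsamples": d.n_subsamples,
        "year_index": None if d.year_index is None else d.year_index.tolist(),
        "species": list(data.y),
    }
    with open(out / "design.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in truth.items()},
                fh,
                indent=1,
            )


def read_dataset(in_dir) -> DetectionData:
    """Read a dataset directory written by :func:`write_dataset`."""
    src = Path(in_dir)
    with open(src / "design.json") as fh:
        meta = json.load(fh)
    mask_df = pd.read_csv(src / "mask.csv")
    I, J = meta["n_sites"], meta["n_occasions"]
    mask = np.zeros((I, J), dtype=bool)
    mask[mask_df["site"] - 1, mask_df["occasion"] - 1] = mask_df["observed"].astype(bool)
    design = StudyDesign(
        n_sites=I,
        n_occasions=J,
        n_subsamples=meta["n_subsamples"],
        year_index=None if meta["year_index"] is None else np.asarray(meta["year_index"]),
        observed_mask=mask,
    )
    cov_long = pd.read_csv(src / "covariates.csv", float_precision="round_trip")
    if len(cov_long):
        covs = cov_long.pivot(index="site", columns="name", values="value").sort_index()
        covs = covs.reset_index(drop=True)
        covs.columns.name = None
    else:
        covs = pd.DataFrame(index=range(I))
    y = {sp: read_detection_csv(src / f"detections_{sp}.csv", design) for sp in meta["species"]}
    return DetectionData(design=design, y=y, covariates=covs)
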