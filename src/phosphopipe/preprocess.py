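"""Filtering, normalization, calibration, and sample-level QC.

The chain mirrors the standard TMT phosphoproteomics workflow: keep class-I
sites (localization probability >= 0.75), scale every site's and protein's
intensities to a within-row mean of 1, then divide each site's normalized
values by its parent protein's normalized values so that phosphorylation
changes are read net of protein-abundance changes. Sites whose parent protein
was not quantified keep their normalized values and are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ProteinRecord, SiteRecord, StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class QuantMatrix:
    """An id x channel intensity matrix with a processing-level tag.

    ``data`` has row ids (site or protein ids) as the index and channel ids
    as columns; missing values are NaN. ``level_tag`` is one of ``raw``,
    ``normalized``, ``calibrated``.
    """

    data: pd.DataFrame
    level_tag: str = "raw"

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CalibrationFlag:
    site_id: str
    protein_quantified: bool


def sites_to_matrix(sites: Iterable[SiteRecord], design: StudyDesign) -> QuantMatrix:
    """Assemble site records into a raw QuantMatrix (channel order from design)."""
    records = list(sites)
    data = pd.DataFrame(
        [[r.intensities.get(ch, np.nan) for ch in design.channels] for r in records],
        index=[r.site_id for r in records],
        columns=design.channels,
        dtype=float,
    )
    return QuantMatrix(data, "raw")


def proteins_to_matrix(
    proteins: Iterable[ProteinRecord], design: StudyDesign
) -> QuantMatrix:
    records = list(proteins)
    data = pd.DataFrame(
        [[r.intensities.get(ch, np.nan) for ch in design.channels] for r in records],
        index=[r.protein_accession for r in records],
        columns=design.channels,
        dtype=float,
    )
    return QuantMatrix(data, "raw")


def filter_class1(
    sites: list[SiteRecord], threshold: float = 0.75, strict: bool = False
) -> list[SiteRecord]:
    """Keep class-I sites: localization probability >= ``threshold``.

    The boundary is inclusive by default (the conventional class-I
    definition); pass ``strict=True`` for a strictly-greater cut.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} not in [0,1]")
    if strict:
        kept = [s for s in sites if s.localization_probability > threshold]
    else:
        kept = [s for s in sites if s.localization_probability >= threshold]
    logger.info(
        "filter_class1: retained %d / %d sites (threshold %s, %s)",
        len(kept),
        len(sites),
        threshold,
        "strict" if strict else "inclusive",
    )
    return kept


def normalize_rows(m: QuantMatrix) -> QuantMatrix:
    """Divide every row by the mean of its non-missing values.

    Rows whose non-missing values are all <= 0, or that are entirely missing,
    cannot serve as ratio denominators; they are dropped with a warning.
    """
    data = m.data
    means = data.mean(axis=1, skipna=True)
    bad = ~(means > 0) | data.notna().sum(axis=1).eq(0)
    if bad.any():
        logger.warning(
            "normalize_rows: dropped %d rows with no positive values", int(bad.sum())
        )
    good = data.loc[~bad]
    normalized = good.div(good.mean(axis=1, skipna=True), axis=0)
    return QuantMatrix(normalized, "normalized")


def calibrate_sites(
    site_m: QuantMatrix,
    prot_m: QuantMatrix,
    parent_of: Mapping[str, str],
) -> tuple[QuantMatrix, list[CalibrationFlag]]:
    """Divide normalized site values by the parent protein's normalized values.

    For sites whose protein is present in ``prot_m``, each channel value
    becomes ``site / protein`` (NaN if either is missing or the protein value
    is <= 0). For sites whose protein is absent entirely, the normalized site
    values are used directly and the site is flagged ``protein_quantified=False``.
    """
    if list(site_m.data.columns) != list(prot_m.data.columns):
        raise ValueError("site and protein matrices have different channel order")
    prot = prot_m.data
    out = site_m.data.copy()
    flags: list[CalibrationFlag] = []
    prot_index = set(prot.index)
    for site_id in out.index:
        acc = parent_of.get(site_id)
        if acc is not None and acc in prot_index:
            denom = prot.loc[acc].to_numpy(dtype=float)
            denom = np.where(denom > 0, denom, np.nan)
            out.loc[site_id] = out.loc[site_id].to_numpy(dtype=float) / denom
            flags.append(CalibrationFlag(site_id, True))
        else:
            flags.append(CalibrationFlag(site_id, False))
    n_fallback = sum(not f.protein_quantified for f in flags)
    logger.info(
        "calibrate_sites: %d sites calibrated against proteins, %d used directly",
        len(flags) - n_fallback,
        n_fallback,
    )
    return QuantMatrix(out, "calibrated"), flags


def sample_correlation(m: QuantMatrix, min_rows: int = 3) -> pd.DataFrame:
    """Channel x channel Pearson correlation on pairwise-complete rows.

    Channel pairs with fewer than ``min_rows`` complete rows get NaN with a
    warning.
    """
    corr = m.data.corr(method="pearson", min_periods=min_rows)
    np.fill_diagonal(corr.values, 1.0)
    n_missing = int(np.isnan(corr.values).sum())
    if n_missing:
        logger.warning(
            "sample_correlation: %d channel pairs had < %d complete rows",
            n_missing // 2,
            min_rows,
        )
    return corr


def pca_project(m: QuantMatrix, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Project channels (samples) onto k principal components.

    Rows (sites/proteins) are the features and are mean-centered but not
    scaled — the values are already ratio-normalized to a common scale. Rows
    with any missing value are excluded. Returns the channel scores and the
    variance-explained fractions.
    """
    if k > len(m.data.columns):
        raise ValueError(
            f"k={k} exceeds the number of channels ({len(m.data.columns)})"
        )
    complete = m.data.dropna(axis=0)
    if complete.shape[0] < 1:
        raise ValueError("no complete rows available for PCA")
    X = complete.to_numpy(dtype=float).T  # channels are the observations
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores,
        index=m.data.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return frame, pca.explained_variance_ratio_


def preprocess_experiment(
    sites: list[SiteRecord],
    proteins: list[ProteinRecord],
    design: StudyDesign,
    loc_threshold: float = 0.75,
    strict_threshold: bool = False,
) -> dict:
    """Run the full filter -> normalize -> calibrate chain.

    Returns a dict with the class-I site list, the calibrated matrix, the
    calibration flags, and the normalized matrices, plus funnel counts.
    """
    class1 = filter_class1(sites, loc_threshold, strict=strict_threshold)
    site_norm = normalize_rows(sites_to_matrix(class1, design))
    prot_norm = normalize_rows(proteins_to_matrix(proteins, design))
    parent_of = {s.site_id: s.protein_accession for s in class1}
    calibrated, flags = calibrate_sites(site_norm, prot_norm, parent_of)
    return {
        "class1_sites": class1,
        "site_normalized": site_norm,
        "protein_normalized": prot_norm,
        "calibrated": calibrated,
        "flags": flags,
        "parent_of": parent_of,
        "counts": {
            "sites_total": len(sites),
            "class1": len(class1),
            "quantified_rows": calibrated.data.shape[0],
            "protein_fallback": sum(not f.protein_quantified for f in flags),
        },
    }
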