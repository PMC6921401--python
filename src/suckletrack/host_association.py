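"""Host-gene expression and its association with gut OTUs.

Relative expression follows the 2^-ddCt convention: target Ct is normalised
against a reference gene (dCt) and then against a calibrator condition
(ddCt); by default the calibrator is the mean dCt of the day-0 samples of
the same intestinal segment. OTU-gene association uses Spearman rank
correlation between matched relative abundances and relative expression,
with Benjamini-Hochberg adjustment applied jointly across the whole
OTU x gene grid.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import (
    LARGE_INTESTINE,
    SMALL_INTESTINE,
    FeatureTable,
    SampleMetadata,
)
from .errors import AnalysisError, ParseError
from .stats import bh_adjust, mann_whitney


def ddct(ct_target: float, ct_reference: float,
         ct_target_calibrator: float, ct_reference_calibrator: float) -> float:
    """Fold change 2^-[(Ct_t - Ct_ref) - (Ct_t,cal - Ct_ref,cal)]."""
    values = (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator)
    if not all(math.isfinite(v) for v in values):
        raise AnalysisError("non-finite Ct value")
    delta_delta = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return 2.0 ** (-delta_delta)


def read_expression(path) -> tuple[pd.DataFrame, str]:
    """Read a gene x sample expression TSV whose first line flags the mode
    (``# mode=relative`` or ``# mode=ct``)."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "mode=" not in first:
            raise ParseError("expression file must start with a '# mode=...' line")
        mode = first.split("mode=")[1].split()[0].lower()
        if mode not in ("relative", "ct"):
            raise ParseError(f"unknown expression mode {mode!r}")
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    return frame, mode


def relative_expression_from_ct(
    ct: pd.DataFrame,
    reference_gene: str,
    metadata: SampleMetadata | None = None,
    calibrator_day: int = 0,
) -> pd.DataFrame:
    """Convert a gene x sample Ct table to fold changes via ddCt.

    dCt = Ct_gene - Ct_reference per sample. The calibrator dCt is the mean
    over the ``calibrator_day`` samples of the same segment when metadata is
    given, otherwise the grand mean dCt per gene.
    """
    if reference_gene not in ct.index:
        raise AnalysisError(f"reference gene {reference_gene!r} not in expression table")
    dct = ct.drop(index=reference_gene).sub(ct.loc[reference_gene], axis=1)
    if metadata is None:
        calib = dct.mean(axis=1)
        return 2.0 ** (-(dct.sub(calib, axis=0)))
    meta = metadata.frame
    out = pd.DataFrame(index=dct.index, columns=dct.columns, dtype=float)
    for seg, block in meta.loc[meta.index.intersection(dct.columns)].groupby("environment"):
        cols = list(block.index)
        ref_cols = list(block.index[block["day"] == calibrator_day])
        if not ref_cols:
            raise AnalysisError(f"no day-{calibrator_day} calibrator samples for {seg!r}")
        calib = dct[ref_cols].mean(axis=1)
        out[cols] = 2.0 ** (-(dct[cols].sub(calib, axis=0)))
    return out


def correlate_otu_gene(
    table: FeatureTable,
    expression: pd.DataFrame,
    otus=None,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Spearman rho/p for every (OTU, gene) over matched samples, with a
    jointly BH-adjusted q column."""
    shared = [s for s in table.sample_ids if s in expression.columns]
    if len(shared) < min_pairs:
        raise AnalysisError("fewer matched samples than min_pairs")
    rel = table.relative_abundance()[shared]
    expr = expression[shared]
    if otus is None:
        otus = table.feature_ids
    rows = []
    for gene in expr.index:
        y = expr.loc[gene].to_numpy(dtype=float)
        if np.all(y == y[0]):
            raise AnalysisError(f"expression of gene {gene!r} is constant")
        for otu in otus:
            x = rel.loc[otu].to_numpy(dtype=float)
            if np.all(x == x[0]):
                continue  # unobserved/constant OTU carries no rank signal
            rho, p = sps.spearmanr(x, y)
            rows.append(dict(otu=otu, gene=gene, rho=float(rho), p=float(p)))
    if not rows:
        raise AnalysisError("no testable OTU-gene pairs")
    frame = pd.DataFrame(rows)
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    return frame


def assign_enrichment_group(
    table: FeatureTable,
    metadata: SampleMetadata,
    otus=None,
    ratio: float = 1.0,
) -> pd.DataFrame:
    """Label OTUs small- vs large-intestine-enriched by mean relative
    abundance contrast across sink samples (ties go to large intestine); a
    two-sided rank-test p accompanies each label."""
    meta = metadata.frame
    small_ids = [s for s in meta.index
                 if meta.loc[s, "role"] == "sink"
                 and meta.loc[s, "environment"] in SMALL_INTESTINE
                 and s in table.counts.columns]
    large_ids = [s for s in meta.index
                 if meta.loc[s, "role"] == "sink"
                 and meta.loc[s, "environment"] in LARGE_INTESTINE
                 and s in table.counts.columns]
    if not small_ids or not large_ids:
        raise AnalysisError("need sink samples in both intestine classes")
    rel = table.relative_abundance()
    if otus is None:
        otus = table.feature_ids
    rows = []
    for otu in otus:
        x = rel.loc[otu, small_ids].to_numpy(dtype=float)
        y = rel.loc[otu, large_ids].to_numpy(dtype=float)
        if x.sum() == 0 and y.sum() == 0:
            rows.append(dict(otu=otu, group="unlabeled", mean_small=0.0,
                             mean_large=0.0, p=np.nan))
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            _, p = mann_whitney(x, y, alternative="two-sided")
        group = "small_intestine" if x.mean() > ratio * y.mean() else "large_intestine"
        rows.append(dict(otu=otu, group=group, mean_small=float(x.mean()),
                         mean_large=float(y.mean()), p=float(p)))
    return pd.DataFrame(rows)
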