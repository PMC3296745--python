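"""Orthogonal-validation calculators: qPCR copy number, qRT-PCR
normalization, FISH signal ratios, and cross-platform correlation.

These reproduce the arithmetic used to validate array findings with
independent assays; quantities arrive pre-extracted (standard-curve
interpolated amounts or Ct values), never raw fluorescence.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "qpcr_copy_number",
    "qrtpcr_normalize",
    "fold_change_vs_controls",
    "fish_signal_ratio",
    "platform_correlation",
]


def _normalized(target, reference, mode: str, efficiency: float) -> np.ndarray:
    target = np.asarray(target, float)
    reference = np.asarray(reference, float)
    if mode == "quantity":
        if (reference <= 0).any():
            raise ValueError("zero/negative reference quantity")
        return target / reference
    if mode == "ct":
        # lower Ct = more template; efficiency 2 unless stated otherwise
        return efficiency ** -(target - reference)
    raise ValueError(f"unknown qPCR mode {mode!r}")


def qpcr_copy_number(
    samples: pd.DataFrame,
    mode: str = "quantity",
    efficiency: float = 2.0,
) -> pd.Series:
    """Copy number from target/reference qPCR measurements.

    ``samples`` columns: ``sample_id, target, reference, is_control``;
    replicate rows per sample are averaged after normalization.  The copy
    number is ``2 x normalized(sample) / median(normalized over control
    samples)``, so a control sitting at the control median reads exactly 2
    copies.  ``mode='quantity'`` divides standard-curve quantities;
    ``mode='ct'`` uses ``efficiency^-(Ct_target - Ct_reference)``.
    """
    norm = _normalized(samples["target"], samples["reference"], mode, efficiency)
    df = samples.assign(norm=norm)
    per_sample = df.groupby("sample_id", sort=False).agg(
        norm=("norm", "mean"), is_control=("is_control", "first")
    )
    controls = per_sample.loc[per_sample["is_control"], "norm"]
    if len(controls) == 0:
        raise ValueError("no control samples supplied")
    if len(controls) < 3:
        warnings.warn("fewer than 3 control samples; median is fragile")
    med = float(controls.median())
    if med == 0:
        raise ValueError("zero control median")
    cn = 2.0 * per_sample["norm"] / med
    cn.name = "copy_number"
    return cn


def qrtpcr_normalize(target: float, references) -> float:
    """Expression normalized to the median of the reference assays."""
    references = np.asarray(references, float)
    med = float(np.median(references))
    if med == 0:
        raise ValueError("zero reference median")
    return float(target) / med


def fold_change_vs_controls(sample_norm: float, control_norms) -> float:
    """Fold change of a normalized sample value over the control mean."""
    control_norms = np.asarray(control_norms, float)
    return float(sample_norm) / float(control_norms.mean())


def fish_signal_ratio(counts: pd.DataFrame) -> float:
    """Mean target / mean control signal count over the scored nuclei.

    ``counts`` columns: ``target_signals, control_signals`` (one row per
    nucleus).  Fewer than 20 nuclei triggers a warning; the field's
    convention is to score at least 20.
    """
    if len(counts) == 0:
        raise ValueError("no nuclei scored")
    if len(counts) < 20:
        warnings.warn(f"only {len(counts)} nuclei scored (< 20)")
    mc = float(counts["control_signals"].mean())
    if mc == 0:
        raise ValueError("zero mean control signal count")
    return float(counts["target_signals"].mean()) / mc


def platform_correlation(
    microarray: pd.DataFrame, qpcr: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene Pearson correlation between two expression platforms.

    Both frames are genes x samples on the shared sample set; needs >=3
    paired samples per gene.  Genes with zero variance on either platform
    get an NA row.  The frame's ``attrs['mean_r']`` holds the average r
    over testable genes.
    """
    shared = microarray.columns.intersection(qpcr.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 paired samples")
    rows = []
    for gene in microarray.index.intersection(qpcr.index):
        x = microarray.loc[gene, shared].to_numpy(float)
        y = qpcr.loc[gene, shared].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"gene_id": gene, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"gene_id": gene, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows).set_index("gene_id")
    out.attrs["mean_r"] = float(out["r"].mean())
    return out
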