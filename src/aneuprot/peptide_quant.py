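"""Peptide filtering, protein rollup, and copy-number-aware normalization.

SILAC peptides are kept when both heavy and light signal-to-noise are >= 2,
or either is >= 5; a protein's log2 ratio is the median over its peptides.
TMT reporter intensities are first denormalized (multiplied by the MS3 ion
accumulation time), corrected for isotopic overlap between reporter
channels, filtered (zero-timepoint channel and >= 4 of 6 channels at
denormalized intensity >= 20), and rolled up as the ratio of summed
intensities — an intensity-weighted average over peptides.

Matrices are normalized by recentering each strain's log2-ratio
distribution over zero, computing the centering factor only from genes NOT
on that strain's duplicated chromosome (which are genuinely more abundant
and would otherwise bias the factor).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import GeneAnnotation, QuantMatrix

#: minimum signal-to-noise required in both SILAC channels
SILAC_S2N_BOTH = 2.0
#: alternative: minimum signal-to-noise in at least one channel
SILAC_S2N_ONE = 5.0
#: minimum denormalized TMT reporter intensity
TMT_MIN_INTENSITY = 20.0
#: minimum number of TMT channels meeting TMT_MIN_INTENSITY
TMT_MIN_CHANNELS = 4


def silac_peptide_filter(s2n_heavy: float, s2n_light: float) -> bool:
    """Keep a SILAC peptide: both channels >= 2, or either channel >= 5."""
    both = s2n_heavy >= SILAC_S2N_BOTH and s2n_light >= SILAC_S2N_BOTH
    one = max(s2n_heavy, s2n_light) >= SILAC_S2N_ONE
    return bool(both or one)


def silac_filter_table(table: pd.DataFrame) -> pd.Series:
    """Vectorized SILAC filter over a peptide table; returns a keep mask."""
    both = (table["s2n_heavy"] >= SILAC_S2N_BOTH) & (table["s2n_light"] >= SILAC_S2N_BOTH)
    one = table[["s2n_heavy", "s2n_light"]].max(axis=1) >= SILAC_S2N_ONE
    return both | one


def tmt_denormalize(intensities: Sequence[float], accumulation_time: float) -> np.ndarray:
    """Undo the instrument's accumulation-time normalization of reporter ions."""
    if accumulation_time <= 0:
        raise ValueError("accumulation_time must be positive")
    return np.asarray(intensities, dtype=float) * float(accumulation_time)


def tmt_isotope_correct(
    intensities: Sequence[float], impurity_matrix: np.ndarray
) -> np.ndarray:
    """Solve M @ x = observed to undo isotopic overlap between channels.

    ``impurity_matrix[i, j]`` is the fraction of channel j's signal that
    appears in channel i. Negative solutions are clipped to zero (with a
    warning): they arise only from noise near the detection floor.
    """
    M = np.asarray(impurity_matrix, dtype=float)
    observed = np.asarray(intensities, dtype=float)
    if M.shape[0] != M.shape[1] or M.shape[0] != observed.shape[-1]:
        raise ValueError("impurity matrix must be square and match channel count")
    corrected = np.linalg.solve(M, observed)
    if (corrected < 0).any():
        warnings.warn("negative intensities after isotope correction clipped to 0")
        corrected = np.clip(corrected, 0.0, None)
    return corrected


def tmt_turnover_filter(
    table: pd.DataFrame, zero_channel: int, channels: Sequence[str] | None = None
) -> pd.Series:
    """Keep mask: zero-timepoint channel >= 20 and >= 4 of 6 channels >= 20.

    Intensities in ``table`` must already be denormalized.
    """
    if channels is None:
        channels = [c for c in table.columns if c.startswith("intensity_")]
    block = table[list(channels)].to_numpy(dtype=float)
    zero_ok = block[:, zero_channel] >= TMT_MIN_INTENSITY
    enough = (block >= TMT_MIN_INTENSITY).sum(axis=1) >= TMT_MIN_CHANNELS
    return pd.Series(zero_ok & enough, index=table.index)


def silac_protein_ratio(peptide_log2_ratios: Sequence[float]) -> float:
    """Median peptide log2 ratio for one protein."""
    values = np.asarray(peptide_log2_ratios, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no kept peptides for this protein")
    return float(np.median(values))


def tmt_protein_ratio(
    table: pd.DataFrame, numerator_channel: int, denominator_channel: int
) -> float:
    """log2 of (summed numerator intensities / summed denominator intensities).

    Summing intensities before taking the ratio weights each peptide by its
    signal, so bright peptides dominate over noisy dim ones.
    """
    num = float(table[f"intensity_{numerator_channel}"].sum())
    den = float(table[f"intensity_{denominator_channel}"].sum())
    if den <= 0:
        raise ValueError("denominator channel sums to zero; ratio undefined")
    return float(np.log2(num / den))


def rollup_silac(table: pd.DataFrame, apply_filter: bool = True) -> pd.Series:
    """Per-protein median log2(H/L) over kept peptides."""
    kept = table[silac_filter_table(table)] if apply_filter else table
    log2_ratio = np.log2(kept["ratio_hl"].astype(float))
    return log2_ratio.groupby(kept["protein"]).median().rename("log2_ratio")


def rollup_tmt(
    table: pd.DataFrame,
    numerator_channel: int = 1,
    denominator_channel: int = 0,
    impurity_matrix: np.ndarray | None = None,
    apply_filter: bool = True,
    zero_channel: int = 0,
) -> pd.Series:
    """Denormalize, isotope-correct, filter, and roll up a TMT peptide table.

    The default impurity matrix is the identity; empirically derived channel
    cross-contamination values can be supplied as a 6x6 matrix.
    """
    channels = [c for c in table.columns if c.startswith("intensity_")]
    block = table[channels].to_numpy(dtype=float)
    block = block * table["accumulation_time"].to_numpy(dtype=float)[:, None]
    if impurity_matrix is not None:
        M = np.asarray(impurity_matrix, dtype=float)
        block = np.linalg.solve(M, block.T).T
        if (block < 0).any():
            warnings.warn("negative intensities after isotope correction clipped to 0")
            block = np.clip(block, 0.0, None)
    work = pd.DataFrame(block, columns=channels, index=table.index)
    work["protein"] = table["protein"].to_numpy()
    if apply_filter:
        work = work[tmt_turnover_filter(work, zero_channel, channels)]
    out = {}
    for protein, sub in work.groupby("protein", sort=True):
        out[protein] = tmt_protein_ratio(sub, numerator_channel, denominator_channel)
    return pd.Series(out, name="log2_ratio")


def normalize_recenter(
    matrix: QuantMatrix,
    annotation: GeneAnnotation | None = None,
    duplicated: Mapping[str, str | None] | None = None,
) -> tuple[QuantMatrix, dict[str, float]]:
    """Recenter each strain's log2 ratios over zero.

    The centering factor is the median over genes NOT on the strain's
    duplicated chromosome (most proteins are at one-to-one abundance); the
    same shift is applied to every gene so duplicated-gene signal is
    preserved relative to the background. Strains mapping to no duplicated
    chromosome (wild-type controls) are centered on all genes.

    Returns the recentered matrix and the per-strain factor subtracted.
    """
    if duplicated is None:
        duplicated = matrix.duplicated_chromosomes()
    data = matrix.data.copy()
    factors: dict[str, float] = {}
    for strain in data.columns:
        chrom = duplicated.get(strain)
        col = data[strain]
        if chrom is None:
            background = col
        else:
            if annotation is None:
                raise ValueError("annotation required to exclude duplicated genes")
            on_dup = set(annotation.genes_on(chrom))
            background = col[~col.index.isin(on_dup)]
        factor = float(background.median(skipna=True))
        data[strain] = col - factor
        factors[strain] = factor
    return QuantMatrix(data, layer=matrix.layer, condition=matrix.condition), factors
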