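"""Library-quality diagnostics.

Three-nucleotide periodicity power spectrum of 5' mapping positions,
gene-body distribution, saturation of detected genes / unique fragments
under nested downsampling, and between-library count correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import TranscriptModel, index_by_transcript

DEFAULT_METAGENE_WINDOW = 300


@dataclass
class SpectrumResult:
    """Power spectrum of the CDS-start-aligned metagene series.

    ``power`` is normalized so that its sum equals the variance of the
    mean-subtracted series (Parseval); ``peak_frequency`` is the argmax over
    non-zero-frequency bins, in nt^-1.
    """

    frequencies: np.ndarray
    power: np.ndarray
    peak_frequency: float
    series: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency": self.frequencies, "power": self.power})


@dataclass
class SaturationCurve:
    fractions: np.ndarray
    genes_detected: np.ndarray
    unique_fragments: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "genes_detected": self.genes_detected,
                "unique_fragments": self.unique_fragments,
            }
        )


def metagene_series(
    alignments: pd.DataFrame,
    models: list[TranscriptModel],
    window: int = DEFAULT_METAGENE_WINDOW,
) -> np.ndarray:
    """5'-end counts at offsets 0..window-1 downstream of each CDS start,
    summed over transcripts, using CDS-mapped alignments only."""
    by_tid = index_by_transcript(models)
    cds_start = {t: m.cds_start for t, m in by_tid.items()}
    cds_end = {t: m.cds_end for t, m in by_tid.items()}
    tids = alignments["transcript_id"].to_numpy()
    pos = alignments["five_prime_pos"].to_numpy(dtype=np.int64)
    starts = np.array([cds_start[t] for t in tids], dtype=np.int64)
    ends = np.array([cds_end[t] for t in tids], dtype=np.int64)
    in_cds = (pos >= starts) & (pos < ends)
    offsets = pos[in_cds] - starts[in_cds]
    offsets = offsets[offsets < window]
    if offsets.size == 0:
        raise ValueError("no CDS-mapped alignments within the metagene window")
    return np.bincount(offsets, minlength=window).astype(float)


def periodicity_spectrum(
    alignments: pd.DataFrame,
    models: list[TranscriptModel],
    window: int = DEFAULT_METAGENE_WINDOW,
) -> SpectrumResult:
    """DFT power spectrum of the mean-subtracted metagene series.

    Frequencies run over [0, 0.5] nt^-1; total power equals the series
    variance; the reported peak excludes the zero-frequency (DC) bin.
    """
    series = metagene_series(alignments, models, window)
    x = series - series.mean()
    X = np.fft.fft(x)
    full_power = np.abs(X) ** 2 / window**2
    half = window // 2
    freqs = np.arange(half + 1) / window
    power = full_power[: half + 1].copy()
    if window % 2 == 0:
        power[1:half] *= 2.0
    else:
        power[1:] *= 2.0
    peak = float(freqs[1:][np.argmax(power[1:])])
    return SpectrumResult(frequencies=freqs, power=power, peak_frequency=peak, series=series)


def gene_body_distribution(
    alignments: pd.DataFrame, models: list[TranscriptModel]
) -> pd.Series:
    """Fractions of alignments whose 5' ends fall in UTR5 / CDS / UTR3;
    sums to 1."""
    if len(alignments) == 0:
        raise ValueError("no alignments")
    by_tid = index_by_transcript(models)
    counts = {"utr5": 0, "cds": 0, "utr3": 0}
    for tid, p in zip(
        alignments["transcript_id"].to_numpy(), alignments["five_prime_pos"].to_numpy()
    ):
        counts[by_tid[tid].region_of(int(p))] += 1
    total = sum(counts.values())
    return pd.Series({k: v / total for k, v in counts.items()}, name="fraction")


def saturation_analysis(
    alignments: pd.DataFrame,
    fractions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    seed: int = 0,
) -> SaturationCurve:
    """Genes detected and unique fragments at nested subsample fractions.

    A single permutation (fixed seed) is drawn and each fraction takes a
    prefix, so the curves are monotone by construction and the value at
    fraction 1.0 equals the full-data statistic.
    """
    fracs = np.asarray(sorted(fractions), dtype=float)
    if ((fracs < 0) | (fracs > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    n = len(alignments)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    genes = alignments["gene_id"].to_numpy()[order]
    keys = (
        alignments["transcript_id"].astype(str)
        + ":"
        + alignments["five_prime_pos"].astype(str)
        + ":"
        + alignments["length"].astype(str)
    ).to_numpy()[order]
    genes_detected = []
    unique_fragments = []
    for f in fracs:
        k = int(round(f * n))
        genes_detected.append(len(np.unique(genes[:k])))
        unique_fragments.append(len(np.unique(keys[:k])))
    return SaturationCurve(
        fractions=fracs,
        genes_detected=np.array(genes_detected),
        unique_fragments=np.array(unique_fragments),
        seed=seed,
    )


def count_correlation(table_a: pd.Series, table_b: pd.Series) -> float:
    """Pearson r between log2(count+1) per-gene counts on shared genes."""
    genes = table_a.index.intersection(table_b.index)
    if len(genes) < 2:
        raise ValueError("need at least two shared genes")
    a = np.log2(table_a.loc[genes].to_numpy(dtype=float) + 1.0)
    b = np.log2(table_b.loc[genes].to_numpy(dtype=float) + 1.0)
    r, _ = stats.pearsonr(a, b)
    return float(r)
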