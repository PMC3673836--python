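"""Pedigree ranking by multinomial likelihood over binned segment lengths.

Post-processed autozygous segments are classified into 5-Mbp length
bins starting at the 2-Mbp minimum-length cutoff (edges 2-7, 7-12, ...
Mbp, top bin open-ended).  For each pedigree model, bin probabilities
are estimated from the segments pooled over all simulation replicates
(with a small pseudocount so no bin has probability zero), and the
observed callset is scored by the multinomial probability of its bin
counts.  Models are ranked by log-likelihood; ties are reported, never
silently broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import ModelRun
from .roh import ROHSegment

__all__ = [
    "LengthBinning",
    "ModelScore",
    "bin_counts",
    "fit_model_probs",
    "multinomial_loglik",
    "rank_models",
]


@dataclass(frozen=True)
class LengthBinning:
    """Left-closed, right-open length bins; the last bin is open-ended."""

    min_length: int = 2_000_000
    bin_width: int = 5_000_000
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.n_bins < 1:
            raise ValueError("bin_width and n_bins must be positive")

    @property
    def edges(self) -> np.ndarray:
        """Closed-bin left edges plus the open top bin's left edge."""
        return self.min_length + self.bin_width * np.arange(self.n_bins)

    def index_of(self, length: int) -> int:
        if length < self.min_length:
            raise ValueError(
                f"segment of {length} bp is below the {self.min_length} bp cutoff; "
                "post-process segments before binning"
            )
        return min((length - self.min_length) // self.bin_width, self.n_bins - 1)


def _lengths(segments) -> np.ndarray:
    out = []
    for s in segments:
        if isinstance(s, ROHSegment):
            out.append(s.length)
        elif isinstance(s, (int, np.integer)):
            out.append(int(s))
        else:  # (chrom, start, end)
            out.append(int(s[2]) - int(s[1]))
    return np.asarray(out, dtype=np.int64)


def bin_counts(segments, binning: LengthBinning = LengthBinning()) -> np.ndarray:
    """Counts per length bin; accepts segments, tuples or raw lengths."""
    counts = np.zeros(binning.n_bins, dtype=np.int64)
    for length in _lengths(segments):
        counts[binning.index_of(int(length))] += 1
    return counts


def fit_model_probs(pooled_counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Smoothed multinomial bin probabilities from pooled simulated counts."""
    c = np.asarray(pooled_counts, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if c.sum() == 0 and pseudocount == 0:
        raise ValueError("all-zero counts with zero pseudocount")
    p = c + pseudocount
    return p / p.sum()


def multinomial_loglik(observed: np.ndarray, probs: np.ndarray) -> float:
    """Log multinomial pmf of the observed bin counts under ``probs``."""
    obs = np.asarray(observed, dtype=np.int64)
    p = np.asarray(probs, dtype=float)
    if obs.shape != p.shape:
        raise ValueError("observed counts and probabilities differ in length")
    n = int(obs.sum())
    if n <= 0:
        raise ValueError("need at least one observed segment")
    return float(stats.multinomial.logpmf(obs, n=n, p=p))


@dataclass(frozen=True)
class ModelScore:
    model_id: str
    log_likelihood: float
    bin_probabilities: np.ndarray = field(repr=False)
    n_observed_segments: int = 0
    mean_segment_count: float = float("nan")
    mean_autozygous_fraction: float = float("nan")
    is_top: bool = False


def rank_models(
    observed_segments,
    model_runs: dict[str, ModelRun],
    binning: LengthBinning = LengthBinning(),
    pseudocount: float = 0.5,
    tie_tol: float = 1e-9,
) -> pd.DataFrame:
    """Score the observed callset against every simulated pedigree model.

    Returns a table sorted by log-likelihood (descending) with an
    ``is_top`` flag that marks every model tied with the best score, and
    per-model diagnostics (mean simulated segment count and mean
    autozygous fraction).  An empty observed callset is an error: with
    no ROH there is no inbreeding signal to rank pedigrees on.
    """
    obs = bin_counts(observed_segments, binning)
    if obs.sum() == 0:
        raise ValueError(
            "observed callset is empty: no runs of homozygosity means no "
            "inbreeding signal; pedigree ranking is not meaningful"
        )
    rows = []
    for model_id, run in model_runs.items():
        pooled = bin_counts(run.pooled_lengths, binning)
        probs = fit_model_probs(pooled, pseudocount)
        ll = multinomial_loglik(obs, probs)
        rows.append(
            dict(
                model_id=model_id,
                log_likelihood=ll,
                n_observed_segments=int(obs.sum()),
                mean_segment_count=run.mean_segment_count,
                mean_autozygous_fraction=run.mean_autozygous_fraction,
            )
        )
    df = pd.DataFrame(rows).sort_values(
        ["log_likelihood", "model_id"], ascending=[False, True]
    ).reset_index(drop=True)
    best = df["log_likelihood"].iloc[0]
    df["is_top"] = df["log_likelihood"] >= best - tie_tol
    return df
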