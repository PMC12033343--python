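"""Expression profiling: TPM normalisation, tissue-specificity calls and
Tukey-HSD significance letters.

The tissues of interest are the pistil side (style/stigma) and the male
side (stamen, germinated pollen): a pistil S-RNase should be
style-specific, a pollen-side F-box the converse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.libqsturng import psturng

TISSUES = ("style_stigma", "stamen", "pollen")
MALE_TISSUES = ("stamen", "pollen")


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) with tissue metadata and gene lengths."""

    counts: pd.DataFrame  # index: gene ids; columns: sample ids
    tissue: dict[str, str]  # sample id -> tissue
    lengths: dict[str, float]  # gene id -> effective length in bp

    def __post_init__(self) -> None:
        for s in self.counts.columns:
            if s not in self.tissue:
                raise ValueError(f"sample {s} has no tissue label")
        for g in self.counts.index:
            L = self.lengths.get(g, 0)
            if not L or L <= 0:
                raise ValueError(f"gene {g} has non-positive length")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")


@dataclass
class TissueProfile:
    gene_id: str
    mean_tpm: dict[str, float]
    profile: str  # style_specific / male_specific / broad / silent
    fold_difference: float  # focal mean vs max other-tissue mean (pseudocount 0.5)


def counts_to_tpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalised rate rescaled so every
    sample column sums to 1e6 (all-zero samples stay zero, with a warning)."""
    lengths = np.array([matrix.lengths[g] for g in matrix.counts.index], dtype=float)
    rate = matrix.counts.values / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(
            f"all-zero sample(s): {list(matrix.counts.columns[zero])}", stacklevel=2
        )
    colsum[zero] = 1.0
    tpm = rate / colsum[None, :] * 1e6
    return pd.DataFrame(tpm, index=matrix.counts.index, columns=matrix.counts.columns)


def tissue_means(tpm: pd.DataFrame, tissue: dict[str, str]) -> pd.DataFrame:
    """Mean TPM per gene per tissue."""
    groups = pd.Series({s: tissue[s] for s in tpm.columns})
    return tpm.T.groupby(groups).mean().T


def tissue_specificity(
    tpm: pd.DataFrame,
    tissue: dict[str, str],
    gene_id: str,
    tau_on: float = 1.0,
    tau_high: float = 10.0,
) -> TissueProfile:
    """Classify a gene's tissue profile from mean TPMs.

    ``style_specific``: style/stigma mean >= tau_high and both male tissues
    below tau_on; ``male_specific`` is the symmetric call (both male tissues
    considered jointly, either >= tau_high); ``silent`` when everything is
    below tau_on; otherwise ``broad``.
    """
    present = sorted({tissue[s] for s in tpm.columns})
    missing = [t for t in TISSUES if t not in present]
    if missing:
        raise ValueError(f"missing tissue(s) {missing}; present: {present}")
    means = tissue_means(tpm, tissue).loc[gene_id]
    style = means["style_stigma"]
    male = [means[t] for t in MALE_TISSUES]
    if style >= tau_high and all(m < tau_on for m in male):
        profile = "style_specific"
        focal, others = style, male
    elif max(male) >= tau_high and style < tau_on:
        profile = "male_specific"
        focal, others = max(male), [style]
    elif style < tau_on and all(m < tau_on for m in male):
        profile = "silent"
        focal, others = style, male
    else:
        profile = "broad"
        focal, others = means.max(), [m for m in means if m != means.max()] or [0.0]
    fold = (focal + 0.5) / (max(others) + 0.5)
    return TissueProfile(
        gene_id=gene_id,
        mean_tpm={t: float(means[t]) for t in TISSUES},
        profile=profile,
        fold_difference=float(fold),
    )


def fold_difference(tpm: pd.DataFrame, tissue: dict[str, str], gene_a: str, gene_b: str, focal_tissue: str = "style_stigma") -> float:
    """Ratio of two genes' mean TPM in a focal tissue (pseudocount 0.5)."""
    means = tissue_means(tpm, tissue)
    return float((means.loc[gene_a, focal_tissue] + 0.5) / (means.loc[gene_b, focal_tissue] + 0.5))


# ---------------------------------------------------------------------------
# Tukey HSD compact letter display


@dataclass
class TukeyResult:
    letters: dict[str, str]  # group -> letter string
    means: dict[str, float]
    not_different: set[tuple[str, str]] = field(repr=False, default_factory=set)


def _tukey_not_different(samples: dict[str, np.ndarray], alpha: float) -> set[tuple[str, str]]:
    """All-pairs Tukey HSD with a pooled error term; returns the pairs NOT
    significantly different at level alpha."""
    names = sorted(samples)
    k = len(names)
    n_total = sum(len(v) for v in samples.values())
    df_err = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
    mse = sse / df_err if df_err > 0 else 0.0
    pairs: set[tuple[str, str]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            na, nb = len(samples[a]), len(samples[b])
            se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
            if se == 0:
                diff = abs(samples[a].mean() - samples[b].mean()) > 0
                if not diff:
                    pairs.add((a, b))
                continue
            # psturng's interpolation misbehaves for extreme q; cap it
            q = min(abs(samples[a].mean() - samples[b].mean()) / se, 50.0)
            p = psturng(q, k, df_err)
            p = float(np.atleast_1d(p)[0])
            if p >= alpha:
                pairs.add((a, b))
    return pairs


def _compact_letters(names_by_mean: list[str], not_different: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display; deterministic given order."""

    def nd(a: str, b: str) -> bool:
        return (a, b) in not_different or (b, a) in not_different

    letter_sets: list[set[str]] = []
    for g in names_by_mean:
        placed = False
        for s in letter_sets:
            if all(nd(g, other) for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in names_by_mean}
    for idx, s in enumerate(letter_sets):
        for g in names_by_mean:
            if g in s:
                letters[g].append(alphabet[idx % len(alphabet)])
    return {g: "".join(v) for g, v in letters.items()}


def tukey_groups(
    values: pd.DataFrame | dict[str, np.ndarray],
    alpha: float = 0.05,
    log_transform: bool = True,
) -> TukeyResult:
    """Tukey-HSD significance letters over replicate groups.

    ``values`` maps group name (e.g. ``gene|tissue``) to replicate TPMs, or
    is a long DataFrame with ``group`` and ``value`` columns.  Analysis runs
    on log2(TPM + 1).  Groups sharing no letter differ significantly at
    ``alpha``.  Letter assignment orders groups by descending mean, so the
    output is independent of input order.
    """
    if isinstance(values, pd.DataFrame):
        samples = {
            str(g): sub["value"].to_numpy(dtype=float)
            for g, sub in values.groupby("group")
        }
    else:
        samples = {str(g): np.asarray(v, dtype=float) for g, v in values.items()}
    if not samples:
        raise ValueError("no groups")
    if any(len(v) < 2 for v in samples.values()) and len(samples) > 1:
        raise ValueError("every group needs >= 2 replicates")
    if log_transform:
        samples = {g: np.log2(v + 1.0) for g, v in samples.items()}
    means = {g: float(v.mean()) for g, v in samples.items()}
    if len(samples) == 1:
        g = next(iter(samples))
        return TukeyResult({g: "a"}, means, set())
    order = sorted(samples, key=lambda g: (-means[g], g))
    nd = _tukey_not_different(samples, alpha)
    letters = _compact_letters(order, nd)
    return TukeyResult(letters, means, nd)
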