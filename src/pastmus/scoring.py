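"""Per-residue essential scores from before/after effect frequencies.

For each retained deletion or combo key present before selection, the fold
change is its after/before frequency ratio.  Fold changes aggregate onto
residues with length discounting:

    dfc_aa[i]  = w * (single-residue deletion fc at i) + sum_j fc_j / len_j**2
    cmfc_aa[i] =                                         sum_k fc_k / len_k**2

where the sums run over multi-residue deletion keys j (and all combo keys k)
whose residue span contains i.  Substitutions are scored qualitatively: a
residue whose after-selection substitution frequency exceeds
mean + 3 SD of log10 frequencies earns sf_score = 2, else 0.

The aggregate S_i = dfc_aa[i] + cmfc_aa[i] is log10-transformed and z-scored
over residues with S_i > 0; p_i is the upper-tail standard-normal probability
and the essential score is -log10(p_i) + sf_score_i.  Residues are ranked by
descending score with ties broken by residue index.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .reference import CdsReference

__all__ = [
    "fold_changes",
    "aggregate_deletion_fc",
    "aggregate_combo_fc",
    "substitution_cutoff",
    "essential_scores",
    "score_cutoff",
]

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["category", "residue_start", "affected_length", "alt_residues"]


def fold_changes(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Per-key after/before frequency ratios.

    Keys retained in the before library define the universe: a key absent
    after selection is fully depleted (fc = 0); keys appearing only after
    selection have no defined denominator and are excluded (logged).
    """
    merged = before.merge(
        after[KEY_COLUMNS + ["frequency", "read_count"]],
        on=KEY_COLUMNS,
        how="left",
        suffixes=("_before", "_after"),
    )
    merged["frequency_after"] = merged["frequency_after"].fillna(0.0)
    merged["fc"] = merged["frequency_after"] / merged["frequency_before"]
    only_after = len(after) - merged["read_count_after"].notna().sum()
    if only_after:
        logger.info("%d effect keys absent from the before library were excluded", only_after)
    return merged[KEY_COLUMNS + ["frequency_before", "frequency_after", "fc"]]


def _aggregate(
    fcs: pd.DataFrame,
    protein_length: int,
    w: float | None,
    max_affected: int,
) -> np.ndarray:
    out = np.zeros(protein_length, dtype=float)
    for row in fcs.itertuples():
        length = int(row.affected_length)
        if length > max_affected:
            continue
        span = max(length, 1)
        a = int(row.residue_start) - 1
        if w is not None and length == 1:
            out[a] += w * row.fc
            continue
        out[max(a, 0) : min(a + span, protein_length)] += row.fc / span**2
    return out


def aggregate_deletion_fc(
    fcs: pd.DataFrame, protein_length: int, w: float = 1.0, max_affected: int = 3
) -> np.ndarray:
    """Residue-level deletion fold change (single-residue keys weighted w)."""
    dels = fcs[fcs["category"] == "aa_deletion"]
    return _aggregate(dels, protein_length, w, max_affected)


def aggregate_combo_fc(
    fcs: pd.DataFrame, protein_length: int, max_affected: int = 3
) -> np.ndarray:
    """Residue-level combo fold change (1/len^2 discount for every key)."""
    combos = fcs[fcs["category"] == "combo"]
    return _aggregate(combos, protein_length, None, max_affected)


def substitution_cutoff(freq_sub: pd.Series, k_sd: float = 3.0) -> tuple[float, pd.Series]:
    """Noise threshold on log10 substitution frequencies and per-residue sf_score.

    The cutoff is mean + ``k_sd`` * sample SD of log10 of the positive
    frequencies; residues strictly above it score 2, everything else
    (including missing/zero frequencies) scores 0.
    """
    logs = np.log10(freq_sub[freq_sub > 0])
    sf = pd.Series(0, index=freq_sub.index, name="sf_score", dtype=int)
    if len(logs) < 2:
        warnings.warn("fewer than 2 positive substitution frequencies; all sf_score = 0")
        return float("nan"), sf
    cutoff = float(logs.mean() + k_sd * logs.std(ddof=1))
    sf.loc[logs[logs > cutoff].index] = 2
    return cutoff, sf


def essential_scores(
    dfc_aa: np.ndarray,
    cmfc_aa: np.ndarray,
    sf_scores: pd.Series | np.ndarray,
    freq_sub: pd.Series | None = None,
    ref: CdsReference | None = None,
) -> pd.DataFrame:
    """Per-residue essential scores and ranks.

    S_i = dfc_aa[i] + cmfc_aa[i]; residues with S_i > 0 are z-scored on
    log10 S_i, p_i is the upper-tail standard-normal probability of z_i, and
    the score is -log10(p_i) + sf_score_i.  Residues with S_i = 0 contribute
    no quantitative part (p recorded as missing).
    """
    n = len(dfc_aa)
    sf = np.asarray(sf_scores, dtype=float)
    if len(sf) != n or len(cmfc_aa) != n:
        raise ValueError("per-residue vectors must share the protein length")
    S = np.asarray(dfc_aa, dtype=float) + np.asarray(cmfc_aa, dtype=float)
    pos = S > 0
    z = np.full(n, np.nan)
    p = np.full(n, np.nan)
    quant = np.zeros(n)
    if pos.sum() >= 1:
        logs = np.log10(S[pos])
        sd = logs.std(ddof=1) if pos.sum() > 1 else 0.0
        if sd == 0:
            warnings.warn("zero spread in positive aggregate fold changes; all z set to 0")
            zpos = np.zeros(pos.sum())
        else:
            zpos = (logs - logs.mean()) / sd
        z[pos] = zpos
        p[pos] = norm.sf(zpos)
        quant[pos] = -np.log10(p[pos])
    score = quant + sf
    order = sorted(range(n), key=lambda i: (-score[i], i))
    rank = np.empty(n, dtype=int)
    for r, i in enumerate(order, start=1):
        rank[i] = r
    df = pd.DataFrame(
        {
            "residue": np.arange(1, n + 1),
            "dfc_aa": dfc_aa,
            "cmfc_aa": cmfc_aa,
            "sf_score": sf.astype(int),
            "z": z,
            "p": p,
            "essential_score": score,
            "rank": rank,
        }
    )
    if freq_sub is not None:
        df.insert(3, "freq_sub", np.asarray(freq_sub, dtype=float))
    if ref is not None:
        df.insert(1, "ref_aa", list(ref.protein[:n].ljust(n, "X")))
        df.insert(0, "gene", ref.gene_id)
    return df


def score_cutoff(scores, k_sd: float = 3.0) -> tuple[float, list[int]]:
    """Mean + k_sd * SD threshold on essential scores; hits are strictly above.

    ``scores`` may be the score table or a per-residue vector; returns the
    cutoff and the 1-based residues above it.
    """
    if isinstance(scores, pd.DataFrame):
        values = scores["essential_score"].to_numpy(dtype=float)
        residues = scores["residue"].to_numpy()
    else:
        values = np.asarray(scores, dtype=float)
        residues = np.arange(1, len(values) + 1)
    if len(values) < 2:
        raise ValueError("need at least 2 scored residues")
    cutoff = float(values.mean() + k_sd * values.std(ddof=1))
    hits = [int(r) for r, v in zip(residues, values) if v > cutoff]
    return cutoff, hits
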