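"""Effector-level activity profiling and nonparametric statistics.

Aggregates per-pair indel frequencies into PAM base-preference summaries
(the heatmap view of average editing per concrete PAM), classifies repair
outcomes into MMEJ vs NHEJ, computes replicate correlations, ranks
effectors into high/low activity categories, and runs the screen's
nonparametric comparisons (two-tailed Mann-Whitney U; Kruskal-Wallis with
Dunn's post hoc).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import DELETION, RepairType, PairEditingProfile
from .design import GuideTargetPair, PamPattern, expand_pattern


# ---------------------------------------------------------------------------
# PAM summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PamSummary:
    effector: str
    pam_group: str
    mean_frequency: float
    n_targets: int


def summarize_by_pam(frequencies: Mapping[str, float],
                     library: Sequence[GuideTargetPair],
                     groups: Sequence[PamPattern | str],
                     effector: str = "") -> List[PamSummary]:
    """Mean indel frequency per PAM group over included (non-excluded) pairs.

    ``frequencies`` maps pair_id to frequency; excluded pairs are simply
    absent.  Groups may overlap; empty groups yield no summary row.
    """
    by_pair = {p.pair_id: p.pam for p in library}
    out = []
    for group in groups:
        pat = group if isinstance(group, PamPattern) else PamPattern(group)
        members = set(expand_pattern(pat))
        vals = [f for pid, f in frequencies.items()
                if by_pair.get(pid) in members]
        if vals:
            out.append(PamSummary(effector, pat.symbols,
                                  float(np.mean(vals)), len(vals)))
    return out


def pam_summary_frame(summaries: Sequence[PamSummary]) -> pd.DataFrame:
    return pd.DataFrame([{"effector": s.effector, "pam_group": s.pam_group,
                          "mean_frequency": s.mean_frequency,
                          "n_targets": s.n_targets} for s in summaries])


# ---------------------------------------------------------------------------
# Repair pathway classification and spectra
# ---------------------------------------------------------------------------

def classify_pathway(rt: RepairType, reference: str, mh_min: int = 2) -> str:
    """MMEJ iff a single deletion whose junction collapses flanking repeats.

    A deletion (s, L) is microhomology-mediated when the reference carries
    identical sequences of length >= ``mh_min`` at s and s+L, so that either
    copy survives the junction.  Every other outcome (insertions,
    multi-event types, repeat-free deletions) is NHEJ.
    """
    if not rt.events:
        raise ValueError("repair type has no events")
    if len(rt.events) != 1 or rt.events[0].kind != DELETION:
        return "NHEJ"
    ev = rt.events[0]
    s, L = ev.start, ev.length
    n = len(reference)
    k = 0
    while s + k < n - L and reference[s + k] == reference[s + L + k]:
        k += 1
    return "MMEJ" if k >= mh_min else "NHEJ"


def repair_type_spectrum(profile: PairEditingProfile
                         ) -> List[Tuple[RepairType, float]]:
    """Each repair type's share of the edited reads, sorted descending."""
    total = profile.edited_total
    if total == 0:
        return []
    spectrum = [(rt, rt.count / total) for rt in profile.repair_types()]
    spectrum.sort(key=lambda t: -t[1])
    return spectrum


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p_value: float
    groups: Tuple[str, ...] = ()


def replicate_correlation(freq_a: Mapping[str, float],
                          freq_b: Mapping[str, float]) -> StatResult:
    """Pearson r of indel frequencies over pairs included in both replicates."""
    shared = sorted(set(freq_a) & set(freq_b))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared pairs; need >= 3")
    r, p = sps.pearsonr([freq_a[k] for k in shared], [freq_b[k] for k in shared])
    return StatResult("pearson", float(r), float(p), ("A", "B"))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group A via rank sums (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[:len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2


def compare_two(group_a: Sequence[float], group_b: Sequence[float],
                exact_max_n: int = 16) -> StatResult:
    """Two-tailed Mann-Whitney U test.

    Small samples (n_A + n_B <= ``exact_max_n``) use exact enumeration of
    all group assignments of the pooled values (valid under ties); larger
    samples use the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    if a.size + b.size <= exact_max_n:
        pooled = np.concatenate([a, b])
        n = pooled.size
        centre = a.size * b.size / 2
        dev_obs = abs(u_obs - centre)
        hits = total = 0
        for idx in itertools.combinations(range(n), a.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - centre) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return StatResult("mann_whitney_u", float(u_obs), min(p, 1.0), ("A", "B"))


def compare_many(groups: Mapping[str, Sequence[float]],
                 adjust: str = "bonferroni") -> List[StatResult]:
    """Kruskal-Wallis H (tie-corrected) plus Dunn's pairwise post hoc tests.

    Dunn z statistics use pooled midranks with the tie correction; pairwise
    p values are adjusted by the configured method ('bonferroni' or 'none').
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use compare_two for two groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    h, p = sps.kruskal(*arrays)
    results = [StatResult("kruskal_wallis", float(h), float(p), tuple(labels))]

    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    i = 0
    for arr in arrays:
        mean_ranks.append(ranks[i:i + arr.size].mean())
        i += arr.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (12 * (n - 1))
    var_base = n * (n + 1) / 12 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for (i, la), (j, lb) in itertools.combinations(enumerate(labels), 2):
        se = math.sqrt(var_base * (1 / arrays[i].size + 1 / arrays[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_ij = 2 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_ij = min(1.0, p_ij * n_pairs)
        elif adjust != "none":
            raise ValueError(f"unknown adjustment {adjust!r}")
        results.append(StatResult("dunn_posthoc", float(z), float(p_ij), (la, lb)))
    return results


# ---------------------------------------------------------------------------
# Effector ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedEffector:
    effector: str
    mean_frequency: float
    category: str  # 'high' or 'low'


def rank_effectors(means: Mapping[str, float],
                   threshold: float = 0.20) -> List[RankedEffector]:
    """Sort effectors by mean frequency and split at the activity threshold.

    'high' iff mean >= threshold (the screen's descriptive 20% split);
    ties are broken by effector name for a stable ordering.
    """
    if not means:
        raise ValueError("no effectors to rank")
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return [RankedEffector(name, float(m), "high" if m >= threshold else "low")
            for name, m in ranked]
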