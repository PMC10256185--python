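"""Precision/recall, score calibration, protein inference, and
parameter-recovery estimators.

Read-level PR curves sweep a descending score threshold over the
peptide-read matches, counting a match as correct when the predicted dye
seq equals the generating one. The *predicted* PR curve replaces 0/1
correctness with each match's own score, so it can be computed without
truth labels; on a well-calibrated classifier the two curves agree.

Peptide and protein scores roll up read scores with a max rule, penalizing
ambiguity: a read identifying a dye seq shared by n peptides contributes
score/n to each, and a peptide shared by n proteins contributes score/n to
each protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np

from fluoroseq.params import SequencingParams
from fluoroseq.prm import PRM
from fluoroseq.proteome import DyeSeq
from fluoroseq.simulator import emit_raw_reads, simulate_dye_tracks


@dataclass
class PRCurve:
    """Ordered sweep points; ``recall`` is non-decreasing."""

    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray

    def interp_precision(self, recall_grid: np.ndarray) -> np.ndarray:
        """Precision at given recall values, linearly interpolated between
        sweep points (clipped to the achieved recall range)."""
        grid = np.clip(recall_grid, self.recall[0], self.recall[-1])
        return np.interp(grid, self.recall, self.precision)

    def average_precision(self) -> float:
        """Area under the sweep in recall, using step weights."""
        r = np.concatenate([[0.0], self.recall])
        return float(np.sum(np.diff(r) * self.precision))


def _sweep(scores: np.ndarray, contrib: np.ndarray, denom: float) -> PRCurve:
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    c = contrib[order]
    cum_c = np.cumsum(c)
    cum_n = np.arange(1, len(s) + 1, dtype=float)
    # tie blocks are processed all at once: keep the last index of each block
    is_block_end = np.ones(len(s), dtype=bool)
    is_block_end[:-1] = s[:-1] != s[1:]
    ends = np.flatnonzero(is_block_end)
    return PRCurve(
        recall=cum_c[ends] / denom,
        precision=cum_c[ends] / cum_n[ends],
        thresholds=s[ends],
    )


def pr_curve(prms: Sequence[PRM], total_relevant: Optional[int] = None) -> PRCurve:
    """Truth-based precision/recall sweep over peptide-read matches."""
    if not prms:
        raise ValueError("no matches")
    if any(p.truth is None for p in prms):
        raise ValueError("pr_curve requires truth labels on every match")
    scores = np.array([p.score for p in prms])
    correct = np.array([float(p.correct) for p in prms])
    denom = float(total_relevant if total_relevant is not None else len(prms))
    return _sweep(scores, correct, denom)


def predicted_pr_curve(prms: Sequence[PRM]) -> PRCurve:
    """Truth-free PR sweep treating each match as fractionally correct
    with probability equal to its score."""
    if not prms:
        raise ValueError("no matches")
    scores = np.array([p.score for p in prms])
    return _sweep(scores, scores.copy(), float(len(prms)))


def entity_pr_curve(entity_scores: Dict, relevant: Iterable) -> PRCurve:
    """PR sweep over scored entities (peptides or proteins); an entity is
    correct when it is truly present, and recall is measured against the
    number of truly present entities."""
    relevant = set(relevant)
    if not entity_scores:
        raise ValueError("no scored entities")
    if not relevant:
        raise ValueError("no relevant entities")
    keys = sorted(entity_scores)
    scores = np.array([entity_scores[k] for k in keys])
    correct = np.array([float(k in relevant) for k in keys])
    return _sweep(scores, correct, float(len(relevant)))


@dataclass
class CalibrationTable:
    """Per-bucket mean predicted score vs empirical accuracy."""

    predicted: np.ndarray
    empirical: np.ndarray
    counts: np.ndarray
    reduced: bool = False  # fewer matches than requested buckets

    def mean_absolute_deviation(self) -> float:
        return float(np.mean(np.abs(self.predicted - self.empirical)))


def calibration_table(prms: Sequence[PRM], n_buckets: int = 100) -> CalibrationTable:
    """Sort matches by score and split them into ``n_buckets`` equal-count
    buckets (any remainder spread one-per-bucket over the leading
    buckets); report per-bucket mean score and fraction correct."""
    if any(p.truth is None for p in prms):
        raise ValueError("calibration requires truth labels")
    n = len(prms)
    if n == 0:
        raise ValueError("no matches")
    reduced = n < n_buckets
    if reduced:
        warnings.warn(f"only {n} matches; reducing bucket count from {n_buckets}")
        n_buckets = n
    scores = np.array([p.score for p in prms])
    correct = np.array([float(p.correct) for p in prms])
    order = np.argsort(-scores, kind="stable")
    scores, correct = scores[order], correct[order]
    base, rem = divmod(n, n_buckets)
    sizes = np.full(n_buckets, base, dtype=int)
    sizes[:rem] += 1
    stops = np.cumsum(sizes)
    starts = stops - sizes
    pred = np.array([scores[a:b].mean() for a, b in zip(starts, stops)])
    emp = np.array([correct[a:b].mean() for a, b in zip(starts, stops)])
    return CalibrationTable(predicted=pred, empirical=emp, counts=sizes, reduced=reduced)


# --------------------------------------------------------------------- #
# peptide / protein roll-up


def score_peptides(prms: Sequence[PRM], reference: Sequence[DyeSeq]) -> Dict:
    """Peptide score = max over reads of (read score / number of peptides
    sharing the read's winning dye seq)."""
    by_id = {ds.dye_seq_id: ds for ds in reference}
    out: Dict = {}
    for p in prms:
        ds = by_id[p.dye_seq_id]
        peptides = sorted(set(ds.peptides))
        share = p.score / len(peptides)
        for pep in peptides:
            if share > out.get(pep, 0.0):
                out[pep] = share
    return out


def peptide_protein_map(reference: Sequence[DyeSeq]) -> Dict:
    """peptide -> sorted list of parent protein ids, over the reference."""
    out: Dict = {}
    for ds in reference:
        for pep, prot in ds.sources:
            out.setdefault(pep, set()).add(prot)
    return {pep: sorted(prots) for pep, prots in out.items()}


def score_proteins(peptide_scores: Dict, pep_to_prot: Dict) -> Dict:
    """Protein score = max over its peptides of (peptide score / number of
    proteins sharing that peptide)."""
    out: Dict = {}
    for pep, score in peptide_scores.items():
        prots = pep_to_prot.get(pep, [])
        if not prots:
            continue
        share = score / len(prots)
        for prot in prots:
            if share > out.get(prot, 0.0):
                out[prot] = share
    return out


# --------------------------------------------------------------------- #
# parameter recovery from designed simulations


@dataclass(frozen=True)
class ParameterEstimate:
    name: str
    value: float
    stderr: float
    n: int


def _single_label_params(base: SequencingParams, **overrides) -> SequencingParams:
    return SequencingParams.create(
        1,
        p=overrides.get("p", float(base.p[0])),
        m=overrides.get("m", float(base.m[0])),
        e=overrides.get("e", base.e),
        d=overrides.get("d", base.d),
        mu=float(base.mu[0]),
        sigma=float(base.sigma[0]),
        sigma_bg=float(base.sigma_bg[0]),
        num_timesteps=overrides.get("num_timesteps", base.num_timesteps),
    )


_ONE_LABEL = DyeSeq.from_code("0", 1)


def estimate_dud_rate(
    params: SequencingParams, n: int, rng: np.random.Generator
) -> ParameterEstimate:
    """Dud rate m from the fraction of single-label tracks dark at t=0,
    with every other error rate zeroed (the only way a track can be dark
    at the first image is a missing fluorophore)."""
    design = _single_label_params(params, p=0.0, e=0.0, d=0.0, num_timesteps=1)
    counts = simulate_dye_tracks(_ONE_LABEL, n, design, rng)
    dark = counts[:, 0, 0] == 0
    m_hat = dark.mean()
    se = np.sqrt(m_hat * (1.0 - m_hat) / n)
    return ParameterEstimate("m", float(m_hat), float(se), n)


def estimate_edman_failure_rate(
    params: SequencingParams, n: int, rng: np.random.Generator
) -> ParameterEstimate:
    """Edman failure rate e from the fraction of tracks whose first-residue
    dye survives to t=1 when detachment, bleaching and duds are off: the
    dye is only still there if the cycle removed nothing."""
    design = _single_label_params(params, p=0.0, m=0.0, d=0.0, num_timesteps=2)
    counts = simulate_dye_tracks(_ONE_LABEL, n, design, rng)
    still = counts[:, 1, 0] == 1
    e_hat = still.mean()
    se = np.sqrt(e_hat * (1.0 - e_hat) / n)
    return ParameterEstimate("e", float(e_hat), float(se), n)


def estimate_detach_rate(
    params: SequencingParams, n: int, rng: np.random.Generator
) -> ParameterEstimate:
    """Detachment rate d by geometric maximum likelihood on the cycle at
    which the signal disappears, with Edman always failing (e=1) and
    bleaching/duds off so detachment is the only loss process. Censored
    tracks (signal present at the last image) contribute exposure only."""
    design = _single_label_params(params, p=0.0, m=0.0, e=1.0)
    T = design.num_timesteps
    if T < 2:
        raise ValueError("detachment estimation needs at least two timesteps")
    counts = simulate_dye_tracks(_ONE_LABEL, n, design, rng)
    present = counts[:, :, 0] > 0  # (n, T); non-increasing in t
    survived_cycles = present[:, 1:].sum(axis=1)  # cycles survived, 0..T-1
    events = ~present[:, T - 1]
    trials = np.where(events, survived_cycles + 1, T - 1)
    total_trials = trials.sum()
    d_hat = events.sum() / total_trials
    se = np.sqrt(d_hat * (1.0 - d_hat) / total_trials)
    return ParameterEstimate("d", float(d_hat), float(se), n)


def estimate_bleach_rate(
    params: SequencingParams, n: int, rng: np.random.Generator
) -> ParameterEstimate:
    """Bleaching rate p from one-step survival of a single fluorophore
    with Edman always failing and detachment/duds off."""
    design = _single_label_params(params, m=0.0, d=0.0, e=1.0, num_timesteps=2)
    counts = simulate_dye_tracks(_ONE_LABEL, n, design, rng)
    lost = counts[:, 1, 0] == 0
    p_hat = lost.mean()
    se = np.sqrt(p_hat * (1.0 - p_hat) / n)
    return ParameterEstimate("p", float(p_hat), float(se), n)


def estimate_intensity_params(
    params: SequencingParams, n: int, rng: np.random.Generator
) -> tuple:
    """(mu, sigma) estimates from single-fluorophore intensities at t=0
    with the dud rate zeroed: the sample mean recovers mu, and
    sqrt(sample variance - sigma_bg^2) recovers the per-fluorophore sd by
    moment matching. Standard errors by the delta method."""
    if n < 2:
        raise ValueError("need at least two reads")
    design = _single_label_params(params, m=0.0, num_timesteps=1)
    counts = simulate_dye_tracks(_ONE_LABEL, n, design, rng)
    y = emit_raw_reads(counts, design, rng)[:, 0, 0]
    mu_hat = y.mean()
    var = y.var(ddof=1)
    excess = var - float(design.sigma_bg[0]) ** 2
    if excess <= 0:
        raise ValueError("sample variance below background: no per-dye signal")
    sigma_hat = np.sqrt(excess)
    se_mu = y.std(ddof=1) / np.sqrt(n)
    # Var(s^2) ~ (mu4 - var^2)/n; delta method through sqrt(s^2 - c)
    centered = y - mu_hat
    mu4 = np.mean(centered**4)
    se_var = np.sqrt(max(mu4 - var**2, 0.0) / n)
    se_sigma = se_var / (2.0 * sigma_hat)
    return (
        ParameterEstimate("mu", float(mu_hat), float(se_mu), n),
        ParameterEstimate("sigma", float(sigma_hat), float(se_sigma), n),
    )


def recover_error_rates(
    params: Optional[SequencingParams] = None,
    n: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> Dict:
    """Run every designed-simulation estimator and return a dict of
    ParameterEstimate keyed by parameter name (m, e, d, p, mu, sigma)."""
    if params is None:
        params = SequencingParams.create(1)
    if rng is None:
        rng = np.random.default_rng()
    if n < 2:
        raise ValueError("n too small to carry any signal")
    ests = {
        "m": estimate_dud_rate(params, n, rng),
        "e": estimate_edman_failure_rate(params, n, rng),
        "d": estimate_detach_rate(params, n, rng),
        "p": estimate_bleach_rate(params, n, rng),
    }
    mu_est, sigma_est = estimate_intensity_params(params, n, rng)
    ests["mu"] = mu_est
    ests["sigma"] = sigma_est
    return ests
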