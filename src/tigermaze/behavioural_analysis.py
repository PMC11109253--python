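"""Descriptive behavioural statistics over session logs.

All functions are pure tabulations of the session tables (plus, where
stated, model belief trajectories): listen proportions by trial index,
confidence-condition transition structure, and entropy-vs-confidence
contrasts.  Statistical tests are the standard ones (Wilcoxon signed-rank,
Pearson correlation) called from scipy, not re-derived.  Trials with missed
responses are excluded from every confidence-conditioned tabulation.

Confidence conditions combine the two binary reports: index 0 = t/g,
1 = t/G, 2 = T/g, 3 = T/G, lowercase meaning low confidence in the tiger
(t) or grid (g) prediction and uppercase high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONDITION_NAMES = ("t/g", "t/G", "T/g", "T/G")


def _condition(conf_td: bool, conf_gr: bool) -> int:
    return 2 * int(conf_td) + int(conf_gr)


def as_cohort(participants) -> dict:
    """Normalize a list of ParticipantData (or a pid -> sessions mapping)
    into a pid -> list[GameRecord] dict."""
    if isinstance(participants, dict):
        return participants
    return {p.participant_id: p.sessions for p in participants}


# -- listening over trials ---------------------------------------------------


@dataclass
class ListenByTrial:
    table: pd.DataFrame          # participant, trial_index (1-based), p_listen
    correlation: float           # Pearson r of p_listen against trial index
    pvalue: float


def listen_proportion_by_trial(participants) -> ListenByTrial:
    """Per trial index, the fraction of Listen choices among scored action
    trials, and the Pearson correlation of that fraction with the trial
    index across (participant, trial-index) means.  The correlation is
    reported as NaN when it is undefined (e.g. all-Listen sessions)."""
    cohort = as_cohort(participants)
    rows = []
    for pid, sessions in cohort.items():
        counts: dict = {}
        for game in sessions:
            for t, trial in enumerate(game.trials):
                if trial.missed_action or trial.action is None:
                    continue
                n_lis, n_tot = counts.get(t + 1, (0, 0))
                counts[t + 1] = (n_lis + (trial.action.kind == "listen"),
                                 n_tot + 1)
        for idx, (n_lis, n_tot) in sorted(counts.items()):
            rows.append({"participant": pid, "trial_index": idx,
                         "p_listen": n_lis / n_tot, "n_trials": n_tot})
    table = pd.DataFrame(rows)
    x = table["trial_index"].to_numpy(dtype=float)
    y = table["p_listen"].to_numpy(dtype=float)
    if len(table) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return ListenByTrial(table, float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return ListenByTrial(table, float(r), float(p))


# -- confidence transition structure ----------------------------------------


@dataclass
class ConfidenceTransitions:
    occupancy: np.ndarray        # (4,) median occurrence probability
    trans_listen: np.ndarray     # (4, 4) median row-normalized transitions
    trans_move: np.ndarray
    freq_listen: np.ndarray      # (4, 4) median occupancy-weighted frequencies
    freq_move: np.ndarray
    per_participant: pd.DataFrame


def confidence_transition_analysis(participants) -> ConfidenceTransitions:
    """Occupancy of the four confidence conditions, per-action 4x4
    transition matrices P(condition_t | condition_{t-1}, action_t) and their
    occupancy-weighted frequencies, medians across participants.

    A transition is counted when two consecutive trials of a game both
    carry complete confidence reports and the second trial's action was
    made; rows never visited are NaN."""
    cohort = as_cohort(participants)
    occ_list, rows = [], []
    tl_list, tm_list, fl_list, fm_list = [], [], [], []
    for pid, sessions in cohort.items():
        occ = np.zeros(4)
        counts = {"listen": np.zeros((4, 4)), "move": np.zeros((4, 4))}
        for game in sessions:
            conds = [
                _condition(tr.conf_td, tr.conf_grid)
                if tr.conf_td is not None and tr.conf_grid is not None
                else None
                for tr in game.trials]
            for c in conds:
                if c is not None:
                    occ[c] += 1
            for t in range(1, len(game.trials)):
                trial = game.trials[t]
                if (conds[t - 1] is None or conds[t] is None
                        or trial.missed_action or trial.action is None):
                    continue
                counts[trial.action.kind][conds[t - 1], conds[t]] += 1
        total = occ.sum()
        occ_p = occ / total if total else np.full(4, np.nan)
        trans = {}
        freq = {}
        for kind in ("listen", "move"):
            rowsum = counts[kind].sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                trans[kind] = np.where(rowsum > 0, counts[kind] / rowsum, np.nan)
            freq[kind] = occ_p[:, None] * trans[kind]
        occ_list.append(occ_p)
        tl_list.append(trans["listen"]); tm_list.append(trans["move"])
        fl_list.append(freq["listen"]); fm_list.append(freq["move"])
        rows.append({"participant": pid,
                     **{f"occ_{name}": occ_p[i]
                        for i, name in enumerate(CONDITION_NAMES)}})
    with warnings.catch_warnings():
        # transitions out of never-visited conditions are NaN by design
        warnings.simplefilter("ignore", RuntimeWarning)
        return ConfidenceTransitions(
            occupancy=np.nanmedian(occ_list, axis=0),
            trans_listen=np.nanmedian(tl_list, axis=0),
            trans_move=np.nanmedian(tm_list, axis=0),
            freq_listen=np.nanmedian(fl_list, axis=0),
            freq_move=np.nanmedian(fm_list, axis=0),
            per_participant=pd.DataFrame(rows))


# -- entropy vs confidence ---------------------------------------------------


@dataclass
class EntropyConfidenceSummary:
    per_participant: pd.DataFrame
    tests: dict                  # name -> (statistic, pvalue)


def entropy_confidence_contrasts(participants, traces) -> EntropyConfidenceSummary:
    """Per participant: mean posterior entropy by reported confidence level
    (both chains), mean prior entropy by the action subsequently chosen,
    and the within-participant correlation between the two posterior
    entropies separately for Listen and Move trials; plus paired Wilcoxon
    tests across participants.

    ``traces`` maps participant id to the per-game model trajectories
    (aligned with the session logs trial by trial)."""
    cohort = as_cohort(participants)
    if not isinstance(traces, dict):
        traces = {p.participant_id: p.traces for p in traces}
    rows = []
    for pid, sessions in cohort.items():
        buckets = {k: [] for k in (
            "td_low", "td_high", "gr_low", "gr_high",
            "prior_td_listen", "prior_td_move",
            "prior_gr_listen", "prior_gr_move")}
        pairs = {"listen": ([], []), "move": ([], [])}
        for game, trace in zip(sessions, traces[pid]):
            u_td = trace.post_entropy_td
            u_gr = trace.post_entropy_gr
            pu_td = trace.prior_entropy_td
            pu_gr = trace.prior_entropy_gr
            for t, trial in enumerate(game.trials):
                if trial.conf_td is not None:
                    buckets["td_high" if trial.conf_td else "td_low"].append(u_td[t])
                if trial.conf_grid is not None:
                    buckets["gr_high" if trial.conf_grid else "gr_low"].append(u_gr[t])
                if not trial.missed_action and trial.action is not None:
                    kind = trial.action.kind
                    buckets[f"prior_td_{kind}"].append(pu_td[t])
                    buckets[f"prior_gr_{kind}"].append(pu_gr[t])
                    pairs[kind][0].append(u_td[t])
                    pairs[kind][1].append(u_gr[t])
        row = {"participant": pid}
        for k, xs in buckets.items():
            row[k] = float(np.mean(xs)) if xs else float("nan")
        for kind in ("listen", "move"):
            x, y = map(np.asarray, pairs[kind])
            if x.size >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
                row[f"corr_{kind}"] = float(stats.pearsonr(x, y)[0])
            else:
                row[f"corr_{kind}"] = float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)

    def _paired(a: str, b: str) -> tuple:
        sub = df[[a, b]].dropna()
        if len(sub) < 2 or np.allclose(sub[a], sub[b]):
            return (float("nan"), float("nan"))
        s, p = stats.wilcoxon(sub[a], sub[b])
        return (float(s), float(p))

    tests = {
        "td_entropy_low_vs_high": _paired("td_low", "td_high"),
        "gr_entropy_low_vs_high": _paired("gr_low", "gr_high"),
        "prior_td_listen_vs_move": _paired("prior_td_listen", "prior_td_move"),
        "prior_gr_listen_vs_move": _paired("prior_gr_listen", "prior_gr_move"),
        "corr_listen_vs_move": _paired("corr_listen", "corr_move"),
    }
    return EntropyConfidenceSummary(df, tests)
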