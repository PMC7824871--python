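"""Behavioural scoring, connectivity aggregation, and repeated-measures ANOVA.

Covers the statistical stages around the reservoir: residual-inhibition
change scores and responder labelling from per-minute loudness ratings,
per-channel/per-site aggregation of connection weights, group summary
statistics, and a mixed repeated-measures ANOVA (any number of within
factors, one optional between factor) with Greenhouse-Geisser correction and
partial eta squared.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .channels import CHANNELS_64, TEMPORAL_CHANNELS, site_of

log = logging.getLogger(__name__)

RESPONDER = "responder"
NONRESPONDER = "nonresponder"


@dataclass
class LoudnessSeries:
    """Per-minute tinnitus loudness ratings (1-9) with phase markers.

    ``final_baseline_index`` is the last rating before stimulation;
    ``first_post_index`` the first rating after stimulus offset.
    """

    ratings: list[int]
    phases: list[str]
    final_baseline_index: int
    first_post_index: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ratings) != len(self.phases):
            raise ValueError("ratings and phases must align")
        if any(not 1 <= r <= 9 for r in self.ratings):
            raise ValueError("ratings must be integers in [1, 9]")
        if not 0 <= self.final_baseline_index < self.first_post_index < len(self.ratings):
            raise ValueError("phase indices invalid (need final baseline < first post)")


def ari_change(series: LoudnessSeries) -> int:
    """Residual-inhibition change score: first post-offset rating minus the
    final baseline rating (negative = suppression, i.e. ARI)."""
    return int(
        series.ratings[series.first_post_index]
        - series.ratings[series.final_baseline_index]
    )


def classify_responder(change_c: int, change_am: int) -> str:
    """Responder iff loudness dropped after both constant and AM stimulation."""
    return RESPONDER if (change_c < 0 and change_am < 0) else NONRESPONDER


def summarize_column(values) -> tuple[float, float]:
    """(mean, sample SD) rounded half-up to 1 decimal place."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValueError("need at least two values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))

    def r1(x: float) -> float:
        return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    return r1(mean), r1(sd)


def etap2_from_f(f_stat: float, df1: float, df2: float) -> float:
    """Partial eta squared implied by an F statistic and its dfs."""
    return f_stat * df1 / (f_stat * df1 + df2)


# ---------------------------------------------------------------------------
# connectivity-weight aggregation


def channel_weight_profile(model, use_abs: bool = True) -> pd.Series:
    """Mean |weight| around each EEG channel's input neuron.

    For every channel the aggregation neighbourhood is its input neuron plus
    that neuron's direct connection partners; the profile value is the mean
    absolute weight over connections incident to the neighbourhood.  Works on
    trained models and on subtraction deltas (whose signed differences are
    taken in absolute value).  A channel with no incident connections gets 0
    with a warning.
    """
    if model.mapping is None:
        raise ValueError("model has no input mapping")
    src, dst = model.src, model.dst
    w = np.abs(model.weights) if use_abs else model.weights
    values = {}
    for label, neuron in model.mapping.channel_to_neuron.items():
        direct = (src == neuron) | (dst == neuron)
        hood = set(src[direct]) | set(dst[direct]) | {neuron}
        hood_arr = np.fromiter(hood, dtype=np.int64)
        incident = np.isin(src, hood_arr) | np.isin(dst, hood_arr)
        if not incident.any():
            log.warning("channel %s has no incident connections; profile set to 0", label)
            values[label] = 0.0
        else:
            values[label] = float(w[incident].mean())
    return pd.Series(values, name="weight")


def group_sites(profile: pd.Series) -> pd.DataFrame:
    """Aggregate a 64-channel profile into 5 sites x 2 hemispheres.

    Midline (z) channels are excluded; each lateral channel contributes to
    exactly one (hemisphere, site) cell; cell value is the mean of member
    channels.  Returns a tidy frame (hemisphere, site, value).
    """
    missing = [c for c in CHANNELS_64 if c not in profile.index]
    if missing:
        raise ValueError(f"profile is missing channels: {missing}")
    cells: dict[tuple[str, str], list[float]] = {}
    for label in profile.index:
        assignment = site_of(str(label))  # raises on unknown labels
        if assignment is None:
            continue
        cells.setdefault(assignment, []).append(float(profile[label]))
    rows = [
        {"hemisphere": h, "site": s, "value": float(np.mean(v))}
        for (h, s), v in sorted(cells.items())
    ]
    return pd.DataFrame(rows)


def temporal_delta(profile_t1: pd.Series, profile_t2: pd.Series) -> float:
    """Mean change (T2 - T1) over the eight temporal-region channels."""
    for p in (profile_t1, profile_t2):
        missing = [c for c in TEMPORAL_CHANNELS if c not in p.index]
        if missing:
            raise ValueError(f"profile missing temporal channels: {missing}")
    diffs = [
        float(profile_t2[c]) - float(profile_t1[c]) for c in TEMPORAL_CHANNELS
    ]
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels x levels-1) orthonormal contrast matrix (columns sum to 0)."""
    dummy = np.eye(levels) - 1.0 / levels
    q, _ = np.linalg.qr(dummy)
    # keep the levels-1 columns spanning the centred space
    keep = [i for i in range(levels) if not np.allclose(q[:, i] @ dummy, 0)]
    c = q[:, keep[: levels - 1]]
    if c.shape[1] != levels - 1:  # degenerate qr pivoting; fall back to Helmert
        c = np.zeros((levels, levels - 1))
        for j in range(levels - 1):
            c[: j + 1, j] = 1.0
            c[j + 1, j] = -(j + 1)
            c[:, j] /= np.linalg.norm(c[:, j])
    return c


def _type3_between(z: np.ndarray, groups: np.ndarray):
    """Per-column Type-III SS for intercept and group on design [1 | group].

    ``z``: (n_subjects x d); returns (ss_intercept, ss_group, rss, df_group).
    """
    n, d = z.shape
    labels = list(dict.fromkeys(groups))
    g = len(labels)
    if g == 1:
        x = np.ones((n, 1))
        terms = {"intercept": [0]}
    else:
        x = np.ones((n, g))
        for j, lab in enumerate(labels[:-1]):
            col = np.where(groups == lab, 1.0, 0.0) - np.where(
                groups == labels[-1], 1.0, 0.0
            )
            x[:, 1 + j] = col
        terms = {"intercept": [0], "group": list(range(1, g))}
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ z  # (p x d)
    resid = z - x @ beta
    rss = float((resid**2).sum())
    ss = {}
    for name, cols in terms.items():
        b = beta[cols, :]
        vinv = np.linalg.inv(xtx_inv[np.ix_(cols, cols)])
        ss[name] = float(sum(b[:, j] @ vinv @ b[:, j] for j in range(d)))
    return ss.get("intercept", 0.0), ss.get("group", 0.0), rss, g - 1


def _gg_epsilon(z: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance of
    orthonormal contrast scores."""
    d = z.shape[1]
    if d <= 1:
        return 1.0
    centred = z.astype(float).copy()
    n_used = 0
    for lab in dict.fromkeys(groups):
        sel = groups == lab
        centred[sel] -= z[sel].mean(axis=0)
        n_used += sel.sum() - 1
    if n_used < 1:
        return 1.0
    cov = centred.T @ centred / n_used
    tr = np.trace(cov)
    denom = d * np.trace(cov @ cov)
    if denom <= 0:
        return 1.0
    eps = tr**2 / denom
    return float(min(1.0, max(1.0 / d, eps)))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: str | None = None,
) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA on a long-format table.

    All ``within`` factors are within-subject; ``between`` (optional) is a
    between-subjects grouping.  The design must be complete and balanced
    across within-factor cells (one observation per subject per cell, or
    several, which are averaged).  For each within effect and its interaction
    with the between factor the error term is the effect-by-subject
    interaction, computed from orthonormal contrast scores; the between
    effect is tested against subjects-within-groups.  Returns a tidy frame
    with F, dfs, Greenhouse-Geisser epsilon and corrected p, and partial eta
    squared.
    """
    for col in [dv, subject, *within] + ([between] if between else []):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    levels = {w: list(dict.fromkeys(data[w])) for w in within}
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    full_cells = list(itertools.product(*(levels[w] for w in within)))
    want = full_cells if len(within) > 1 else [c[0] for c in full_cells]
    missing = [c for c in want if c not in wide.columns]
    if missing or wide.isna().any().any():
        na_cells = list(wide.columns[wide.isna().any(axis=0)]) if not missing else []
        raise ValueError(f"incomplete design; missing cells: {missing or na_cells}")
    wide = wide[want]
    subjects = wide.index.to_numpy()
    y = wide.to_numpy(dtype=float)

    if between is not None:
        grp_map = data.groupby(subject)[between].agg(
            lambda s: s.iloc[0] if s.nunique() == 1 else None
        )
        if grp_map.isna().any():
            raise ValueError("a subject has multiple between-group labels")
        groups = grp_map.loc[subjects].to_numpy()
        n_groups = len(dict.fromkeys(groups))
        if min(np.bincount(pd.factorize(groups)[0])) < 2:
            raise ValueError("each between group needs >= 2 subjects")
    else:
        groups = np.array(["all"] * len(subjects))
        n_groups = 1

    n_subj = len(subjects)
    contrast = {w: _orthonormal_contrasts(len(levels[w])) for w in within}
    mean_vec = {w: np.full((len(levels[w]), 1), 1.0 / len(levels[w])) for w in within}

    rows = []

    def add_row(effect, ss_eff, df1, ss_err, df2, eps):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f_stat = ms_eff / ms_err if ms_err > 0 else np.inf
        p_unc = float(sps.f.sf(f_stat, df1, df2))
        p_gg = float(sps.f.sf(f_stat, df1 * eps, df2 * eps))
        rows.append(
            {
                "effect": effect,
                "SS": ss_eff,
                "df1": df1,
                "df2": df2,
                "SS_error": ss_err,
                "F": f_stat,
                "eps_gg": eps,
                "p": p_unc,
                "p_gg": p_gg,
                "eta_p2": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
            }
        )

    # between effect: per-subject means across all cells
    z0 = y.mean(axis=1, keepdims=True)
    cell_total = y.shape[1]
    if between is not None:
        _, ss_g, rss0, df_g = _type3_between(z0 * np.sqrt(cell_total), groups)
        add_row(between, ss_g, df_g, rss0, n_subj - n_groups, 1.0)

    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            mats = [contrast[w] if w in combo else mean_vec[w] for w in within]
            c_mat = mats[0]
            for m in mats[1:]:
                c_mat = np.kron(c_mat, m)
            # scale so SS matches the full design (averaging shrinks variance)
            m_avg = int(np.prod([len(levels[w]) for w in within if w not in combo]))
            z = (y @ c_mat) * np.sqrt(m_avg)
            d_eff = z.shape[1]
            eps = _gg_epsilon(z, groups)
            ss_int, ss_grp, rss, df_g = _type3_between(z, groups)
            df_err = d_eff * (n_subj - n_groups)
            name = "*".join(combo)
            add_row(name, ss_int, d_eff, rss, df_err, eps)
            if between is not None:
                add_row(f"{name}*{between}", ss_grp, d_eff * df_g, rss, df_err, eps)

    return pd.DataFrame(rows)
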