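"""Derived SCFA measures, temporal responder stratification, and stool AUC."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from microguild.data_model import ScfaProfile, StoolDiary
from microguild.stats import TestResult, friedman_dunn, unpaired_rank_test

RESPONDER = "W6-responder"
NONRESPONDER = "W6-nonresponder"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ScfaDerived:
    """Derived per-sample SCFA measures.

    total = acetate + propionate + butyrate; percentages are each major SCFA
    over that total; the propionate:butyrate ratio is missing when butyrate
    is zero; total branched SCFA = isobutyrate + isovalerate.
    """

    sample_id: str
    total_scfa: float
    pct_acetate: float
    pct_propionate: float
    pct_butyrate: float
    prop_to_but_ratio: float | None
    total_bscfa: float


def derive_scfa_measures(profile: ScfaProfile) -> ScfaDerived:
    total = profile.acetate + profile.propionate + profile.butyrate
    if total <= 0:
        raise ValueError(f"sample {profile.sample_id!r}: total SCFA is zero")
    if profile.butyrate > 0:
        ratio = profile.propionate / profile.butyrate
    else:
        warnings.warn(
            f"sample {profile.sample_id!r}: butyrate is zero, "
            "propionate:butyrate ratio undefined",
            stacklevel=2,
        )
        ratio = None
    return ScfaDerived(
        sample_id=profile.sample_id,
        total_scfa=total,
        pct_acetate=100.0 * profile.acetate / total,
        pct_propionate=100.0 * profile.propionate / total,
        pct_butyrate=100.0 * profile.butyrate / total,
        prop_to_but_ratio=ratio,
        total_bscfa=profile.isobutyrate + profile.isovalerate,
    )


def derived_table(profiles: dict[str, ScfaProfile]) -> pd.DataFrame:
    rows = []
    for sid, p in profiles.items():
        d = derive_scfa_measures(p)
        rows.append(
            {
                "sample_id": sid,
                "total_scfa": d.total_scfa,
                "pct_acetate": d.pct_acetate,
                "pct_propionate": d.pct_propionate,
                "pct_butyrate": d.pct_butyrate,
                "prop_to_but_ratio": (
                    d.prop_to_but_ratio if d.prop_to_but_ratio is not None else np.nan
                ),
                "total_bscfa": d.total_bscfa,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class ResponderLabel:
    """Temporal propionate responder status of one subject.

    Responder when propionate rose from W1 to W6 (delta > 0), nonresponder
    when it fell (delta < 0), indeterminate on an exact tie.
    """

    subject_id: str
    label: str
    delta_w6_w1: float
    propionate_bl: float | None = None


def classify_w6_responder(
    subject_id: str,
    propionate_bl: float | None,
    propionate_w1: float | None,
    propionate_w6: float | None,
) -> ResponderLabel:
    if propionate_w1 is None or propionate_w6 is None:
        warnings.warn(
            f"subject {subject_id!r}: missing W1/W6 propionate; indeterminate",
            stacklevel=2,
        )
        return ResponderLabel(subject_id, INDETERMINATE, math.nan, propionate_bl)
    delta = propionate_w6 - propionate_w1
    if delta > 0:
        label = RESPONDER
    elif delta < 0:
        label = NONRESPONDER
    else:
        label = INDETERMINATE
    return ResponderLabel(subject_id, label, delta, propionate_bl)


def responder_table(labels: list[ResponderLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"subject_id": r.subject_id, "label": r.label, "delta_w6_w1": r.delta_w6_w1}
            for r in labels
        ]
    ).set_index("subject_id")


def responder_group_comparison(
    labels: list[ResponderLabel],
    values: pd.DataFrame,
    timepoints: tuple[str, ...] = ("BL", "W1", "W6"),
) -> dict[str, object]:
    """Within- and between-group tests of a measure across timepoints.

    ``values`` is subjects x timepoints. Within each responder group a
    Friedman test with Dunn-corrected pairwise comparisons runs over the
    timepoints; between groups a Mann-Whitney test runs at each timepoint.
    Indeterminate subjects are excluded; groups below n = 3 skip their tests
    with a warning.
    """
    groups = {
        RESPONDER: [r.subject_id for r in labels if r.label == RESPONDER],
        NONRESPONDER: [r.subject_id for r in labels if r.label == NONRESPONDER],
    }
    out: dict[str, object] = {"within": {}, "between": []}
    for name, members in groups.items():
        members = [m for m in members if m in values.index]
        if len(members) < 3:
            warnings.warn(f"group {name!r} too small for within-group test", stacklevel=2)
            continue
        matrix = values.loc[members, list(timepoints)].to_numpy()
        omnibus, pairwise = friedman_dunn(matrix, list(timepoints))
        out["within"][name] = {"omnibus": omnibus, "pairwise": pairwise}
    between: list[TestResult] = []
    a = [m for m in groups[RESPONDER] if m in values.index]
    b = [m for m in groups[NONRESPONDER] if m in values.index]
    if len(a) >= 3 and len(b) >= 3:
        for tp in timepoints:
            between.append(
                unpaired_rank_test(
                    values.loc[a, tp], values.loc[b, tp], name=f"{tp}"
                )
            )
    else:
        warnings.warn("a responder group is too small for between-group tests",
                      stacklevel=2)
    out["between"] = between
    return out


@dataclass(frozen=True)
class AucSummary:
    subject_id: str
    measure: str
    auc: float


def hedonic_auc(diary: StoolDiary, measure: str = "consistency") -> AucSummary:
    """Linear-trapezoid area under weekly stool scores (unit week spacing).

    Interior missing weeks are linearly interpolated; a missing endpoint is
    an error. For seven weekly points bounded in [0, 4] the AUC lies in
    [0, 24].
    """
    scores = np.asarray(getattr(diary, measure), dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two weekly scores")
    if np.isnan(scores[0]) or np.isnan(scores[-1]):
        raise ValueError("missing endpoint week cannot be interpolated")
    if np.any(np.isnan(scores)):
        idx = np.arange(scores.size)
        good = ~np.isnan(scores)
        scores = np.interp(idx, idx[good], scores[good])
    auc = float(np.trapezoid(scores))
    return AucSummary(diary.subject_id, measure, auc)
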