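"""Limb-by-limb pre/post differencing and side normalization.

Each adjacent pair of gait assessments isolates the re-shoeing of one
forelimb: 'between' minus 'pre' reflects the first re-shod limb, 'post'
minus 'between' the second. Because re-shoeing a left and a right limb are
expected to produce directionally opposite movement changes, the nine
asymmetry difference variables of right-limb interventions are inverted
(multiplied by -1); the three range-of-motion differences carry no
left/right sign and are left untouched. Lunge direction is recoded to
'inside'/'outside' according to whether the re-shod limb was on the inside
of the circle. After normalization, negative asymmetry differences indicate
reduced force production with the re-shod limb.
"""

from __future__ import annotations

from typing import Mapping, Union

import pandas as pd

from .types import (
    ASYMMETRY_DIFF_COLUMNS,
    DIFF_COLUMNS,
    DIFF_TABLE_COLUMNS,
    SUMMARY_METRIC_COLUMNS,
)

_SESSION_PAIRS = (("pre", "between"), ("between", "post"))

RowLike = Union[pd.Series, Mapping[str, object]]


def _direction_of(condition: str, limb: str) -> str:
    if condition == "straight":
        return "straight"
    if condition not in ("left circle", "right circle"):
        raise ValueError(f"unknown exercise condition {condition!r}")
    inner = "left" if condition == "left circle" else "right"
    return "inside" if limb == inner else "outside"


def pre_post_diff(pre: RowLike, post: RowLike) -> pd.Series:
    """Raw post-minus-pre difference record for one condition.

    ``pre`` and ``post`` are condition-summary rows of the same horse,
    surface and exercise condition from adjacent sessions. The resulting
    record keeps the raw exercise condition and attributes the difference
    to the limb re-shod in the later session.
    """
    pre, post = pd.Series(pre), pd.Series(post)
    for key in ("horse_id", "surface", "condition"):
        if pre[key] != post[key]:
            raise ValueError(
                f"cannot pair summaries: {key} differs "
                f"({pre[key]!r} vs {post[key]!r})"
            )
    if (pre["session"], post["session"]) not in _SESSION_PAIRS:
        raise ValueError(
            "sessions must be adjacent (pre->between or between->post), got "
            f"{pre['session']!r} -> {post['session']!r}"
        )
    rec = {
        "horse_id": pre["horse_id"],
        "reshod_limb": post["reshod_limb"],
        "surface": pre["surface"],
        "condition": pre["condition"],
    }
    for c in SUMMARY_METRIC_COLUMNS:
        rec["D" + c] = float(post[c]) - float(pre[c])
    return pd.Series(rec)


def apply_side_inversion(diffs: pd.DataFrame) -> pd.DataFrame:
    """Invert the nine asymmetry differences of right-limb interventions.

    ROM differences are exempt: range of motion has no left/right sign.
    Applying the inversion twice restores the input (involution).
    """
    out = diffs.copy()
    right = out["reshod_limb"] == "right"
    cols = [c for c in ASYMMETRY_DIFF_COLUMNS if c in out.columns]
    out.loc[right, cols] = -out.loc[right, cols]
    return out


def recode_direction(diffs: pd.DataFrame) -> pd.DataFrame:
    """Replace the raw exercise condition by 'straight'/'inside'/'outside'."""
    out = diffs.copy()
    out["direction"] = [
        _direction_of(c, l)
        for c, l in zip(out["condition"], out["reshod_limb"])
    ]
    out = out.drop(columns=["condition"])
    ordered = [c for c in DIFF_TABLE_COLUMNS if c in out.columns]
    return out[ordered]


def side_normalize(diffs: pd.DataFrame) -> pd.DataFrame:
    """Full side normalization: sign inversion plus direction recoding."""
    return recode_direction(apply_side_inversion(diffs))


def build_normalized_dataset(summaries: pd.DataFrame) -> pd.DataFrame:
    """Side-normalized difference dataset from per-condition summaries.

    For every horse, surface and exercise condition, the two adjacent
    session pairs are differenced; the full study design (10 horses x 2
    forelimbs x 4 conditions) yields 80 records.
    """
    rows = []
    keyed = summaries.set_index(["horse_id", "session", "surface", "condition"])
    for (horse, surface, condition), _ in summaries.groupby(
        ["horse_id", "surface", "condition"], sort=False
    ):
        for s_pre, s_post in _SESSION_PAIRS:
            try:
                pre = keyed.loc[(horse, s_pre, surface, condition)]
                post = keyed.loc[(horse, s_post, surface, condition)]
            except KeyError:
                continue
            pre = pre.copy()
            post = post.copy()
            pre["horse_id"], post["horse_id"] = horse, horse
            pre["surface"] = post["surface"] = surface
            pre["condition"] = post["condition"] = condition
            pre["session"], post["session"] = s_pre, s_post
            rows.append(pre_post_diff(pre, post))
    if not rows:
        raise ValueError("no pairable session records found")
    raw = pd.DataFrame(rows).reset_index(drop=True)
    return side_normalize(raw)


def variable_columns(diffs: pd.DataFrame) -> list:
    """The difference-variable columns present in a dataset."""
    return [c for c in DIFF_COLUMNS if c in diffs.columns]
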