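"""Bundled summary tables of the published cohort, and their reproduction.

The original patient scans and per-patient tables were never deposited; what
the study leaves behind are printed group summaries, contingency counts and
test statistics. Those are transcribed into a JSON fixture shipped with the
package, and :func:`reproduce_tables` recomputes every statistic that is
recoverable from them — the chi-squares from the raw counts, the pooled t
statistics from the per-stratum summaries, the whole-class mean CT values as
count-weighted stratum means, and the non-invasive percentage from the
subtype counts — placing computed and printed values side by side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cohortstats import ContingencyTable, GroupSummary, pearson_chi2, pooled_t

__all__ = ["PublishedTables", "FixtureError", "load_fixtures", "reproduce_tables"]

_SCHEMA = "nodulequant.published_tables.v1"


class FixtureError(ValueError):
    """Bundled fixture data failed schema or consistency validation."""


@dataclass(frozen=True)
class PublishedTables:
    """Validated view of the bundled summary tables."""

    cohort: dict
    appearance_hu: dict
    invasiveness: dict
    thresholds: dict

    def contingency(self, covariate: str) -> ContingencyTable:
        entry = self.invasiveness["contingency"][covariate]
        rows = entry["rows"]
        return ContingencyTable(
            counts=np.array(list(rows.values()), dtype=int),
            row_labels=tuple(rows),
        )

    def summary_pair(self, covariate: str) -> tuple[GroupSummary, GroupSummary]:
        entry = self.invasiveness["summaries"][covariate]
        inv = GroupSummary(*_as_summary(entry["invasive"]))
        non = GroupSummary(*_as_summary(entry["noninvasive"]))
        return inv, non


def _as_summary(triple) -> tuple[int, float, float]:
    n, mean, sd = triple
    return int(n), float(mean), float(sd)


def load_fixtures() -> PublishedTables:
    """Load and validate the bundled summary tables.

    Validation enforces the internal consistency of the transcription: the
    subtype counts sum to the cohort total, every contingency column sums to
    the published group sizes, and AIS + MIA equals the non-invasive count.
    """
    text = (
        resources.files("nodulequant") / "data" / "published_tables.json"
    ).read_text()
    raw = json.loads(text)
    if raw.get("schema") != _SCHEMA:
        raise FixtureError(f"unexpected fixture schema: {raw.get('schema')!r}")

    fx = PublishedTables(
        cohort=raw["cohort"],
        appearance_hu=raw["appearance_hu"],
        invasiveness=raw["invasiveness"],
        thresholds=raw["thresholds"],
    )

    subtype_sum = sum(fx.cohort["subtype_counts"].values())
    if subtype_sum != fx.cohort["total"]:
        raise FixtureError(
            f"subtype counts sum to {subtype_sum}, expected {fx.cohort['total']}"
        )
    n_non = sum(
        fx.cohort["subtype_counts"][s] for s in fx.cohort["noninvasive_subtypes"]
    )
    if n_non != fx.invasiveness["n_noninvasive"]:
        raise FixtureError(
            f"AIS+MIA = {n_non} != non-invasive n = {fx.invasiveness['n_noninvasive']}"
        )
    expected_cols = (fx.invasiveness["n_invasive"], fx.invasiveness["n_noninvasive"])
    for cov in fx.invasiveness["contingency"]:
        sums = tuple(fx.contingency(cov).counts.sum(axis=0))
        if sums != expected_cols:
            raise FixtureError(
                f"{cov}: contingency columns sum to {sums}, expected {expected_cols}"
            )
    for cls, entry in fx.appearance_hu.items():
        if cls == "comment":
            continue
        n_whole = entry["whole"][0]
        n_strata = entry["enhanced"][0] + entry["non_enhanced"][0]
        if n_whole != n_strata:
            raise FixtureError(f"{cls}: stratum n's {n_strata} != whole-class n {n_whole}")
    return fx


def reproduce_tables(fixtures: PublishedTables | None = None) -> pd.DataFrame:
    """Recompute every printed statistic recoverable from the bundled tables.

    Returns a DataFrame with columns ``statistic, computed, printed, abs_diff``
    covering: Pearson chi-square per categorical covariate, pooled t per
    appearance class (enhanced vs non-enhanced mean CT), the whole-class mean
    CT values as count-weighted means of the enhancement strata, and the
    non-invasive percentage of the cohort.
    """
    fx = fixtures or load_fixtures()
    rows: list[tuple[str, float, float]] = []

    for cov in fx.invasiveness["contingency"]:
        entry = fx.invasiveness["contingency"][cov]
        chi = pearson_chi2(fx.contingency(cov))
        rows.append((f"chi2_{cov}", chi.chi2, float(entry["printed_chi2"])))

    for cls, entry in fx.appearance_hu.items():
        if cls == "comment":
            continue
        enh = GroupSummary(*_as_summary(entry["enhanced"]))
        non = GroupSummary(*_as_summary(entry["non_enhanced"]))
        t = pooled_t(enh, non)  # sign: non-enhanced minus enhanced
        rows.append((f"t_{cls}", t.t, float(entry["printed_t"])))
        weighted = (enh.n * enh.mean + non.n * non.mean) / (enh.n + non.n)
        rows.append((f"mean_ct_{cls}", weighted, float(entry["whole"][1])))

    n_non = sum(
        fx.cohort["subtype_counts"][s] for s in fx.cohort["noninvasive_subtypes"]
    )
    pct = 100.0 * n_non / fx.cohort["total"]
    rows.append(("noninvasive_pct", pct, 24.5))

    out = pd.DataFrame(rows, columns=["statistic", "computed", "printed"])
    out["abs_diff"] = (out["computed"] - out["printed"]).abs()
    return out
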