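"""Human-readable summaries of a study's detection ledger.

Renders per-block presence grids using the +/- convention with Bayes
strength symbols: "+" anecdotal, "++" moderate, "+++" strong, "++++" very
strong to extreme; methods without entries render as "n/a".
"""

from __future__ import annotations

import math

import pandas as pd

METHOD_ORDER = ["manual-visual", "permutation", "bayes"]
METHOD_LABEL = {
    "manual-visual": "Visual",
    "permutation": "Perm. test",
    "bayes": "Bayes",
}


def bayes_symbol(max_bf10: float) -> str:
    """Evidence-strength symbol for a present Bayes call."""
    if max_bf10 < 1:
        return "-"
    if max_bf10 < 3:
        return "+"
    if max_bf10 < 10:
        return "++"
    if max_bf10 < 30:
        return "+++"
    return "++++"


def _cell(row) -> str:
    if row is None:
        return "n/a"
    if not row["present"]:
        return "-"
    if row["method"] == "bayes" and not (
        row["strength"] is None or (isinstance(row["strength"], float) and math.isnan(row["strength"]))
    ):
        return bayes_symbol(float(row["strength"]))
    return "+"


def presence_grid(ledger: pd.DataFrame, component: str = "MMN") -> pd.DataFrame:
    """Block x (deviant, method) grid of presence symbols for one component."""
    sub = ledger[ledger["component"] == component]
    deviants = sorted(sub["deviant"].unique())
    blocks = sorted(sub["block"].unique())
    subjects = sorted(sub["subject_id"].unique())
    rows = []
    for subject in subjects:
        for block in blocks:
            row = {"subject": subject, "block": block}
            for deviant in deviants:
                for method in METHOD_ORDER:
                    sel = sub[
                        (sub["subject_id"] == subject)
                        & (sub["block"] == block)
                        & (sub["deviant"] == deviant)
                        & (sub["method"] == method)
                    ]
                    key = f"{deviant}:{METHOD_LABEL[method]}"
                    row[key] = _cell(sel.iloc[0]) if len(sel) else "n/a"
            rows.append(row)
    return pd.DataFrame(rows)


def rates_table(rates: pd.DataFrame, component: str = "MMN") -> pd.DataFrame:
    """Detection-rate table in block x (deviant, method) layout."""
    sub = rates[rates["component"] == component]
    out = sub.pivot_table(
        index="block",
        columns=["deviant", "method"],
        values="proportion_present",
    )
    n = sub.groupby("block")["n_subjects"].max()
    out.insert(0, ("", "N"), n)
    return out


def render_report(
    ledger: pd.DataFrame,
    rates: pd.DataFrame | None = None,
    components: tuple[str, ...] = ("MMN", "P3a"),
) -> str:
    """Console report: presence grids, then detection-rate tables."""
    parts = []
    for comp in components:
        if not len(ledger[ledger["component"] == comp]):
            continue
        parts.append(f"== {comp}: per-block presence ==")
        parts.append(presence_grid(ledger, comp).to_string(index=False))
        if rates is not None and len(rates[rates["component"] == comp]):
            parts.append(f"\n== {comp}: detection rates ==")
            parts.append(rates_table(rates, comp).to_string())
        parts.append("")
    return "\n".join(parts)
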