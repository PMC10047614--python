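"""Rendering of fitted-model results as publication-style tables."""

from __future__ import annotations

import pandas as pd

from .glmm import FitResult, classify_effects

_FAMILY_LABEL = {"gaussian": "Gaussian", "gaussian_log": "Gaussian; log transformed",
                 "poisson": "Poisson", "negative_binomial": "negative binomial"}


def results_frame(fits: dict[str, FitResult]) -> pd.DataFrame:
    """One row per term per fitted model, mirroring the reporting layout
    (model, parameter, estimate, SE, statistic, p, CI bounds, family, label)."""
    rows = []
    for label, fit in fits.items():
        marks = classify_effects(fit)
        for term, r in fit.table.iterrows():
            if term == "Intercept":
                continue
            rows.append({
                "model": label,
                "family": _FAMILY_LABEL.get(fit.family, fit.family),
                "parameter": term,
                "estimate": r["estimate"],
                "se": r["se"],
                "statistic": r["statistic"],
                "statistic_kind": fit.statistic_kind,
                "p": r["p"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "label": marks.get(term, "none"),
            })
    return pd.DataFrame(rows)


def render_results_table(fits: dict[str, FitResult]) -> str:
    """Fixed-width text table; significant terms are marked ``*`` and trends
    ``.`` after the p-value, and the statistic column says whether it is a
    z or a t value (t for gaussian fits)."""
    header = (f"{'Model':<32} {'Parameter':<12} {'Estimate':>9} {'SE':>8} "
              f"{'z/t':>8} {'P':>9} {'Lower CI':>9} {'Upper CI':>9}")
    lines = [header, "-" * len(header)]
    frame = results_frame(fits)
    if frame.empty:
        return "\n".join(lines)
    last_model = None
    for _, r in frame.iterrows():
        model = f"{r['model']} ({r['family']})"
        shown = model if model != last_model else ""
        last_model = model
        mark = {"significant": "*", "trend": "."}.get(r["label"], " ")
        stat = f"{r['statistic']:8.3f}" + ("t" if r["statistic_kind"] == "t" else " ")
        lines.append(
            f"{shown:<32} {r['parameter']:<12} {r['estimate']:9.3f} "
            f"{r['se']:8.3f} {stat} {r['p']:8.3f}{mark} "
            f"{r['ci_low']:9.3f} {r['ci_high']:9.3f}")
    lines.append("")
    lines.append("* p < 0.05 (effect); . 0.05 <= p < 0.10 (trend); "
                 "t marks a t statistic (gaussian fits).")
    return "\n".join(lines)
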