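"""Plain-text table rendering for fit results.

Every renderer is a pure function of a stored result dictionary, so any
reported number can be re-derived from the JSON on disk.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "render_enumeration_table",
    "render_growth_table",
    "render_combination_table",
    "render_coefficient_blocks",
    "render_trajectory_table",
    "trajectory_means",
]


def _fmt(x, nd=3):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "."
    return f"{x:.{nd}f}"


def render_enumeration_table(records: list[dict]) -> str:
    """Model-comparison table: one row per candidate class count."""
    lines = [
        f"{'model':<12}{'-2LL':>12}{'BIC':>12}{'aBIC':>12}{'entropy':>10}"
        f"{'min class':>11}{'flags':>12}"
    ]
    for r in records:
        flags = []
        if r.get("degenerate"):
            flags.append("degenerate")
        if not r.get("converged", True):
            flags.append("nonconv")
        lines.append(
            f"{r['model_label']:<12}{r['minus2LL']:>12.1f}{r['bic']:>12.1f}"
            f"{r['abic']:>12.1f}{_fmt(r['entropy']):>10}"
            f"{min(r['class_proportions']):>11.3f}{','.join(flags) or '-':>12}"
        )
    return "\n".join(lines)


def render_growth_table(fit_dict: dict, class_names=None) -> str:
    """Growth-factor estimates per class: means, variances, covariance."""
    weights = fit_dict["weights"]
    means = np.asarray(fit_dict["means"])
    covs = np.asarray(fit_dict["covs"])
    K = len(weights)
    class_names = class_names or [f"class {c + 1}" for c in range(K)]
    lines = [f"{'':<18}" + "".join(f"{nm:>14}" for nm in class_names)]
    lines.append(f"{'weight':<18}" + "".join(f"{w:>14.3f}" for w in weights))
    lines.append(f"{'mean INT':<18}" + "".join(f"{means[c, 0]:>14.3f}" for c in range(K)))
    lines.append(f"{'mean SLP':<18}" + "".join(f"{means[c, 1]:>14.3f}" for c in range(K)))
    lines.append(f"{'var INT':<18}" + "".join(f"{covs[c, 0, 0]:>14.3f}" for c in range(K)))
    lines.append(f"{'var SLP':<18}" + "".join(f"{covs[c, 1, 1]:>14.3f}" for c in range(K)))
    lines.append(f"{'cov INT,SLP':<18}" + "".join(f"{covs[c, 0, 1]:>14.3f}" for c in range(K)))
    return "\n".join(lines)


def render_combination_table(table: list[dict]) -> str:
    """Class counts, proportions and conditional transition probabilities."""
    lines = [
        f"{'combination':<13}{'stage1':>8}{'stage2':>8}{'count':>8}"
        f"{'prop':>8}{'P(trans)':>10}"
    ]
    for row in table:
        lines.append(
            f"{row['combination']:<13}{row['stage1']:>8}{row['stage2']:>8}"
            f"{row['count']:>8}{row['proportion']:>8.3f}"
            f"{row['transition_probability']:>10.3f}"
        )
    return "\n".join(lines)


def render_coefficient_blocks(wald_rows: list[dict]) -> str:
    """Three coefficient blocks (Stage-1, Stage-2, transition) with
    beta / SE / t / p / odds ratio; significance convention p < .001."""
    lines = []
    for block in ("stage1", "stage2", "transition"):
        rows = [r for r in wald_rows if r["block"] == block]
        if not rows:
            continue
        lines.append(f"{block.upper()} block")
        lines.append(
            f"  {'term':<24}{'beta':>9}{'SE':>8}{'t':>9}{'p':>9}{'OR':>10}"
        )
        for r in rows:
            star = " *" if r.get("significant_p001") else ""
            lines.append(
                f"  {r['term']:<24}{r['beta']:>9.2f}{_fmt(r['se'], 2):>8}"
                f"{_fmt(r['t'], 2):>9}{_fmt(r['p'], 3):>9}"
                f"{_fmt(r['odds_ratio'], 2):>10}{star}"
            )
    return "\n".join(lines)


def trajectory_means(fit_dict: dict, time_scores, indicators) -> list[dict]:
    """Model-implied indicator means per class per wave (trajectory summary)."""
    means = np.asarray(fit_dict["means"])
    out = []
    for c in range(len(fit_dict["weights"])):
        for name, t in zip(indicators, time_scores):
            out.append(
                {
                    "class": c + 1,
                    "indicator": name,
                    "time": float(t),
                    "implied_mean": float(means[c, 0] + t * means[c, 1]),
                }
            )
    return out


def render_trajectory_table(rows: list[dict]) -> str:
    lines = [f"{'class':<7}{'indicator':<11}{'time':>7}{'implied mean':>14}"]
    for r in rows:
        lines.append(
            f"{r['class']:<7}{r['indicator']:<11}{r['time']:>7.1f}"
            f"{r['implied_mean']:>14.3f}"
        )
    return "\n".join(lines)
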