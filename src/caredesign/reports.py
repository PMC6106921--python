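"""Report writers: tab-separated tables plus plain-text summaries.

Outputs are deterministic — no timestamps inside data files — so identical
inputs produce byte-identical reports (timestamps belong in logs only).
"""

from __future__ import annotations

from pathlib import Path

from .comparison import OptionComparison
from .costs import CostBreakdown
from .quality import QualityProfile
from .sensitivity import WeightSweepResult


def _bar(value: float, scale: float, width: int = 30) -> str:
    """Plain-text signed bar, for workshop printouts."""
    if scale <= 0:
        return ""
    n = min(width, int(round(abs(value) / scale * width)))
    return ("+" if value >= 0 else "-") * n


def write_profile(profile: QualityProfile, cost: CostBreakdown,
                  out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p1 = out / f"scores_{profile.option_name}.tsv"
    profile.to_frame().to_csv(p1, sep="\t", float_format="%.6f")
    p2 = out / f"costs_{profile.option_name}.tsv"
    cost.to_frame().to_csv(p2, sep="\t", float_format="%.2f")
    return [p1, p2]


def write_comparison(comp: OptionComparison, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = out / "comparison.tsv"
    comp.to_frame().to_csv(table, sep="\t", float_format="%.6f")

    lines = [f"Option {comp.option_b} vs option {comp.option_a}", ""]
    # side-by-side domain scores per category (grouped-bar shape, in text)
    lines.append("Domain scores (per category):")
    fa, fb = comp.profile_a.to_frame(), comp.profile_b.to_frame()
    for cat in fa.index:
        lines.append(f"  category {cat}:")
        for dom in fa.columns:
            lines.append(f"    {dom:<14} {comp.option_a}={fa.at[cat, dom]:6.1f}  "
                         f"{comp.option_b}={fb.at[cat, dom]:6.1f}")
    lines.append("")
    lines.append("Cost vs aggregate quality (annual):")
    for cat, cc in comp.per_category.items():
        lines.append(f"  category {cat:<4} quality {cc.aggregate_delta:+8.2f}  "
                     f"annual cost {cc.annual_cost_delta:+12.2f}  "
                     f"[{cc.quadrant.value}]")
    lines.append("")
    lines.append(f"Service annual cost delta: {comp.annual_cost_delta:+.2f}")
    lines.append(f"Service percentage saving: {comp.percentage_saving:.2f}%")
    summary = out / "comparison_summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    return [table, summary]


def write_weight_sweep(result: WeightSweepResult, out_dir: str | Path,
                       bars: bool = True) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = out / "weight_sweep.tsv"
    result.to_frame().to_csv(table, sep="\t", index=False, float_format="%.6f")

    lines = ["Weight sensitivity of the aggregate quality delta (B - A)", ""]
    scale = max((abs(v) for r in result.rows for v in r.aggregate_deltas.values()),
                default=0.0)
    for cat, base in result.baseline_deltas.items():
        robust = "robust" if result.robustness[cat] else "NOT robust"
        lines.append(f"category {cat}: baseline {base:+.2f} ({robust})")
        if bars:
            for row in result.rows:
                v = row.aggregate_deltas[cat]
                lines.append(f"  {row.domain:<14}{row.delta:+.1f}  {v:+7.2f}  "
                             f"{_bar(v, scale)}")
        lines.append("")
    summary = out / "weight_sweep_summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    return [table, summary]
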