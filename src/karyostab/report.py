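"""Plain-text summary report tying the pipeline stages together.

The report is deterministic: regenerated from the same inputs it is
byte-identical.  The competition-model overlay is the closed form evaluated
on the report grid, so the printed curve is exactly the model, not a
re-interpolation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .competition import CompetitionFit, CompetitionParams, ProportionTrajectory, proportion_xo
from .cnv import BinCallResult
from .growth import DoublingEstimate

__all__ = ["write_report", "format_report"]


def _fmt(x: float, nd: int = 4) -> str:
    return f"{x:.{nd}g}"


def format_report(
    doubling: dict[str, DoublingEstimate] | None = None,
    competition_fit: CompetitionFit | None = None,
    trajectory: ProportionTrajectory | None = None,
    model_params: CompetitionParams | None = None,
    cnv: BinCallResult | None = None,
    chrom_fractions=None,
    seed: int | None = None,
    version: str = "",
) -> str:
    if not any(v is not None for v in (doubling, competition_fit, trajectory, cnv, chrom_fractions)):
        raise ValueError("need at least one stage output to report")
    lines: list[str] = ["# karyostab summary report", ""]
    if seed is not None:
        lines.append(f"seed: {seed}")
    if version:
        lines.append(f"version: {version}")
    if doubling:
        lines += ["", "## Doubling times"]
        for name, est in doubling.items():
            if est.is_growing:
                lines.append(
                    f"{name}: doubling time {_fmt(est.doubling_time_h)} h "
                    f"(95% CI {_fmt(est.ci95_low)}-{_fmt(est.ci95_high)} h, "
                    f"lambda {_fmt(est.lambda_hat)} /h, R2 {_fmt(est.r_squared)}, "
                    f"n={est.n_points})"
                )
            else:
                lines.append(f"{name}: non-growing (lambda <= 0), doubling time undefined")
    if competition_fit is not None:
        lines += ["", "## Competition fit"]
        lines.append(
            f"delta_lambda {_fmt(competition_fit.delta_lambda_hat)} /h "
            f"(s.e. {_fmt(competition_fit.stderr_delta_lambda)}), "
            f"log2 odds at t0 {_fmt(competition_fit.log2_odds0_hat)}, "
            f"R2 {_fmt(competition_fit.r_squared)}, "
            f"n={competition_fit.n_points_used} "
            f"({competition_fit.n_points_dropped} boundary points dropped)"
        )
    if trajectory is not None:
        lines += ["", "## XO proportion trajectory",
                  "time_h\tp_xo_observed" + ("\tp_xo_model" if model_params is not None else "")]
        model = (
            proportion_xo(trajectory.times, model_params)
            if model_params is not None
            else None
        )
        for i, t in enumerate(trajectory.times):
            row = f"{t:g}\t{trajectory.p_xo[i]:.6f}"
            if model is not None:
                row += f"\t{np.atleast_1d(model)[i]:.6f}"
            lines.append(row)
    if cnv is not None:
        lines += ["", "## Copy-number bin calls"]
        lines.append(f"{cnv.n_called} bins called (FDR {cnv.alpha}, |log2FC| >= {cnv.lfc_min})")
        lines.append(
            f"% of assessable genome aberrant: "
            f"{cnv.fraction_genome_called(include_sex=True):.3f} (with chrX/chrY), "
            f"{cnv.fraction_genome_called(include_sex=False):.3f} (autosomes only)"
        )
    if chrom_fractions is not None:
        lines += ["", "## Reads per chromosome (%)"]
        lines.append("chrom\t" + "\t".join(chrom_fractions.columns.astype(str)))
        for chrom, row in chrom_fractions.iterrows():
            lines.append(str(chrom) + "\t" + "\t".join(f"{v:.3f}" for v in row))
    return "\n".join(lines) + "\n"


def write_report(path: str | Path, **kwargs) -> str:
    text = format_report(**kwargs)
    Path(path).write_text(text)
    return text
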