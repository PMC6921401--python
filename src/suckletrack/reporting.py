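"""Paper-style summary tables from stage results.

Pure formatting: these functions rearrange already-computed results and
never recompute statistics, so regenerating a report from stored stage
outputs is byte-identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import SampleMetadata
from .errors import AnalysisError
from .source_tracking import MixingEstimate
from .stats import PermanovaResult

P_DISPLAY_FLOOR = 0.001


def format_p(p: float, floor: float = P_DISPLAY_FLOOR) -> str:
    """Display convention: values below the floor render as '< 0.001'."""
    return f"< {floor:g}" if p < floor else f"{p:.3g}"


def permanova_table(results: dict[str, list[PermanovaResult]]) -> pd.DataFrame:
    """One row per factor; R2, P and display-P columns per distance metric.

    ``results`` maps metric name -> list of per-factor results computed on
    the same sample set; differing sample counts across metrics are an
    error because the rows would not be comparable.
    """
    if not results or all(len(v) == 0 for v in results.values()):
        raise AnalysisError("no PERMANOVA results to tabulate")
    n_samples = {r.n_samples for rs in results.values() for r in rs}
    if len(n_samples) > 1:
        raise AnalysisError(f"metrics computed on different sample sets: n={sorted(n_samples)}")
    factors: list[str] = []
    for rs in results.values():
        for r in rs:
            if r.factor not in factors:
                factors.append(r.factor)
    table = pd.DataFrame(index=pd.Index(factors, name="factor"))
    for metric, rs in results.items():
        by_factor = {r.factor: r for r in rs}
        table[f"{metric}_R2"] = [round(by_factor[f].r_squared, 4) if f in by_factor
                                 else np.nan for f in factors]
        table[f"{metric}_P"] = [by_factor[f].p_value if f in by_factor
                                else np.nan for f in factors]
        table[f"{metric}_P_display"] = [
            format_p(by_factor[f].p_value) if f in by_factor else "" for f in factors]
    return table.reset_index()


def contribution_summary(
    estimates: list[MixingEstimate],
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Long-format (segment, day, environment, mean_proportion, se, n).

    Mean proportions within each (segment, day) sum to 1 up to numerical
    noise because every per-sink posterior mean does.
    """
    if not estimates:
        raise AnalysisError("no mixing estimates to summarise")
    meta = metadata.frame
    rows = []
    for est in estimates:
        if est.sink_id not in meta.index:
            raise AnalysisError(f"estimate for unknown sample {est.sink_id!r}")
        seg = meta.loc[est.sink_id, "environment"]
        if meta.loc[est.sink_id, "role"] != "sink":
            raise AnalysisError(f"{est.sink_id!r} is not a sink sample")
        day = int(meta.loc[est.sink_id, "day"])
        for env, m in est.means.items():
            rows.append(dict(segment=seg, day=day, environment=env, value=m))
    frame = pd.DataFrame(rows)
    out = (frame.groupby(["segment", "day", "environment"])["value"]
           .agg(["mean", "sem", "count"])
           .rename(columns={"mean": "mean_proportion", "sem": "se", "count": "n"})
           .reset_index())
    out["se"] = out["se"].fillna(0.0)
    return out
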