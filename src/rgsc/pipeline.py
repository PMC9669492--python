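"""Full-study orchestration: validate, score, index, correlate, render.

``run_study`` takes a cohort of repertory grids plus the instrument item
table and produces a :class:`StudyReport` holding

* descriptive statistics (bootstrapped means, severity-band frequencies),
* mean element distances with bootstrap CIs and pairwise overlap flags,
* four correlation tables — measures x measures (lower triangle),
  distances x measures, opposed-pole proportions x measures, and
  polarization x measures — each cell a Spearman rho with percentile
  bootstrap CI, t-approximation p-value and significance stars.

One master seed governs every bootstrap; each cell draws from its own
substream derived from (table, row, column), so any single table can be
reproduced in isolation and the whole report is deterministic.

No multiple-testing adjustment is applied by default; Benjamini-Hochberg
within each table is available behind ``adjust_p=True``.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .grid import RepertoryGrid, read_cohort, read_measures_table, validate_grid
from .indexes import compute_indexes, indexes_table
from .measures import score_measures
from .stats import CorrelationCell, MeanWithCI, bootstrap_mean, cis_overlap, correlate

__all__ = [
    "AnalysisConfig",
    "TableCell",
    "StudyReport",
    "run_study",
    "run_study_from_paths",
    "render_tables",
    "tables_long",
    "parse_tables_long",
    "report_to_json",
]

# analysis variables: scored-measure column -> display label
MEASURES = (
    ("phq9_total", "PHQ-9"),
    ("gad7_total", "GAD-7"),
    ("swls_total", "SWLS"),
    ("qolibri_scaled", "QOLIBRI"),
)
DISTANCE_ROWS = (
    ("ed_present_before", "Present self - self before the lesion"),
    ("ed_present_ideal", "Present self - ideal self"),
    ("ed_before_ideal", "Self before the lesion - ideal self"),
)
OPPOSED_ROWS = (
    ("opp_present_before", "Present self - self before the lesion"),
    ("opp_present_ideal", "Present self - ideal self"),
    ("opp_before_ideal", "Self before the lesion - ideal self"),
)
POLARIZATION_ROWS = (
    ("pol_present", "Present self"),
    ("pol_before", "Self before the lesion"),
    ("pol_ideal", "Ideal self"),
    ("pol_total", "Total polarization"),
)


@dataclass(frozen=True)
class AnalysisConfig:
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0
    ci_method: str = "percentile"
    adjust_p: bool = False  # Benjamini-Hochberg within each table


@dataclass(frozen=True)
class TableCell:
    row: str
    col: str
    cell: CorrelationCell


@dataclass
class StudyReport:
    n_participants: int
    descriptives: dict[str, MeanWithCI]
    band_frequencies: dict[str, dict[str, int]]
    mean_distances: dict[str, MeanWithCI]
    distance_overlap: dict[str, bool]
    mean_opposed: dict[str, MeanWithCI]
    mean_polarization: dict[str, MeanWithCI]
    table1: list[TableCell]
    table2: list[TableCell]
    table3: list[TableCell]
    table4: list[TableCell]
    metadata: dict = field(default_factory=dict)


def _cell_seed(master: int, table: int, i: int, j: int) -> int:
    """Stable per-cell substream seed derived from the master seed."""
    ss = np.random.SeedSequence(master, spawn_key=(table, i, j))
    return int(ss.generate_state(1)[0])


def _mean_ci(x, cfg: AnalysisConfig, table: int, i: int) -> MeanWithCI:
    return bootstrap_mean(
        x, n_boot=cfg.n_boot, level=cfg.level, seed=_cell_seed(cfg.seed, table, i, 0)
    )


def _bh_adjust(cells: list[TableCell]) -> list[TableCell]:
    from scipy.stats import false_discovery_control

    if not cells:
        return cells
    adj = false_discovery_control([c.cell.p_value for c in cells], method="bh")
    out = []
    for c, p in zip(cells, adj):
        k = c.cell
        out.append(
            TableCell(
                c.row,
                c.col,
                CorrelationCell(
                    k.rho, k.ci_low, k.ci_high, float(p), k.n, k.n_boot, k.seed
                ),
            )
        )
    return out


def run_study(
    grids: list[RepertoryGrid], measures_df, config: AnalysisConfig = AnalysisConfig()
) -> StudyReport:
    """Run the complete analysis on an in-memory cohort.

    Raises on any invalid grid (with the full validation report) and on
    participant-id mismatch between grids and the measures table.
    """
    problems = []
    for g in grids:
        for v in validate_grid(g):
            problems.append(f"{g.participant_id}: {v}")
    if problems:
        raise ValueError("invalid grids:\n" + "\n".join(problems))

    grid_ids = {g.participant_id for g in grids}
    meas_ids = set(measures_df["participant_id"])
    if grid_ids != meas_ids:
        orphans = sorted(grid_ids ^ meas_ids)
        raise ValueError(f"participant ids do not match across inputs: {orphans}")

    grids = sorted(grids, key=lambda g: g.participant_id)
    scored = score_measures(measures_df).sort_values("participant_id")
    idx = indexes_table(compute_indexes(g) for g in grids)
    merged = idx.merge(scored, on="participant_id").sort_values("participant_id")
    merged = merged.reset_index(drop=True)
    n = len(merged)

    cfg = config
    # --- descriptives (table 0 substream) -------------------------------
    descriptives = {}
    desc_vars = [m for m, _ in MEASURES] + ["qolibri_raw", "n_constructs"]
    for i, col in enumerate(desc_vars):
        descriptives[col] = _mean_ci(merged[col].to_numpy(float), cfg, 0, i)
    band_frequencies = {
        "phq9_band": merged["phq9_band"].value_counts().to_dict(),
        "phq9_binary": merged["phq9_binary"].value_counts().to_dict(),
        "gad7_binary": merged["gad7_binary"].value_counts().to_dict(),
        "swls_band": merged["swls_band"].value_counts().to_dict(),
        "low_hrqol": {
            "low": int(merged["low_hrqol"].sum()),
            "not_low": int(n - merged["low_hrqol"].sum()),
        },
    }

    # --- mean grid indexes with CIs (tables 5-7 substreams) -------------
    mean_distances = {
        col: _mean_ci(merged[col].to_numpy(float), cfg, 5, i)
        for i, (col, _) in enumerate(DISTANCE_ROWS)
    }
    dist_cols = [c for c, _ in DISTANCE_ROWS]
    distance_overlap = {
        f"{a}|{b}": cis_overlap(mean_distances[a], mean_distances[b])
        for ai, a in enumerate(dist_cols)
        for b in dist_cols[ai + 1 :]
    }
    mean_opposed = {
        col: _mean_ci(merged[col].to_numpy(float), cfg, 6, i)
        for i, (col, _) in enumerate(OPPOSED_ROWS)
    }
    mean_polarization = {
        col: _mean_ci(merged[col].to_numpy(float), cfg, 7, i)
        for i, (col, _) in enumerate(POLARIZATION_ROWS)
    }

    # --- correlation tables ---------------------------------------------
    def corr_cell(table, i, j, xcol, ycol):
        return TableCell(
            xcol,
            ycol,
            correlate(
                merged[xcol].to_numpy(float),
                merged[ycol].to_numpy(float),
                n_boot=cfg.n_boot,
                level=cfg.level,
                seed=_cell_seed(cfg.seed, table, i, j),
                method=cfg.ci_method,
            ),
        )

    mcols = [m for m, _ in MEASURES]
    table1 = [
        corr_cell(1, i, j, mcols[i], mcols[j])
        for i in range(1, len(mcols))
        for j in range(i)
    ]
    table2 = [
        corr_cell(2, i, j, row, m)
        for i, (row, _) in enumerate(DISTANCE_ROWS)
        for j, m in enumerate(mcols)
    ]
    table3 = [
        corr_cell(3, i, j, row, m)
        for i, (row, _) in enumerate(OPPOSED_ROWS)
        for j, m in enumerate(mcols)
    ]
    table4 = [
        corr_cell(4, i, j, row, m)
        for i, (row, _) in enumerate(POLARIZATION_ROWS)
        for j, m in enumerate(mcols)
    ]
    if cfg.adjust_p:
        table1, table2, table3, table4 = (
            _bh_adjust(t) for t in (table1, table2, table3, table4)
        )

    digest = _input_digest(grids, measures_df)
    return StudyReport(
        n_participants=n,
        descriptives=descriptives,
        band_frequencies=band_frequencies,
        mean_distances=mean_distances,
        distance_overlap=distance_overlap,
        mean_opposed=mean_opposed,
        mean_polarization=mean_polarization,
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        metadata={
            "seed": cfg.seed,
            "n_boot": cfg.n_boot,
            "level": cfg.level,
            "ci_method": cfg.ci_method,
            "adjust_p": cfg.adjust_p,
            "version": __version__,
            "input_digest": digest,
        },
    )


def _input_digest(grids, measures_df) -> str:
    from .grid import write_grid_table
    import tempfile, os

    h = hashlib.sha256()
    for g in sorted(grids, key=lambda g: g.participant_id):
        h.update(g.participant_id.encode())
        h.update(np.ascontiguousarray(g.ratings, dtype=np.int64).tobytes())
    h.update(measures_df.sort_values("participant_id").to_csv(index=False).encode())
    return h.hexdigest()


def run_study_from_paths(grid_dir, measures_path, config=AnalysisConfig()):
    grids = read_cohort(grid_dir)
    measures = read_measures_table(measures_path)
    return run_study(grids, measures, config)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_LABELS = dict(MEASURES) | dict(DISTANCE_ROWS) | dict(OPPOSED_ROWS) | dict(POLARIZATION_ROWS)


def _cell_dict(tc: TableCell, table: str) -> dict:
    c = tc.cell
    return {
        "table": table,
        "row_var": tc.row,
        "col_var": tc.col,
        "rho": c.rho,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "p": c.p_value,
        "stars": c.stars,
        "n": c.n,
        "n_boot": c.n_boot,
        "seed": c.seed,
    }


def tables_long(report: StudyReport):
    """All correlation cells as one tidy long-format DataFrame."""
    import pandas as pd

    rows = []
    for name, cells in (
        ("table1", report.table1),
        ("table2", report.table2),
        ("table3", report.table3),
        ("table4", report.table4),
    ):
        rows.extend(_cell_dict(tc, name) for tc in cells)
    return pd.DataFrame(rows)


def parse_tables_long(path) -> dict[str, list[TableCell]]:
    """Parse the long-format CSV back into cells (round-trips with
    :func:`tables_long`)."""
    import pandas as pd

    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    out: dict[str, list[TableCell]] = {}
    for rec in df.to_dict("records"):
        cell = CorrelationCell(
            float(rec["rho"]),
            float(rec["ci_low"]),
            float(rec["ci_high"]),
            float(rec["p"]),
            int(rec["n"]),
            int(rec["n_boot"]),
            int(rec["seed"]),
        )
        out.setdefault(rec["table"], []).append(
            TableCell(rec["row_var"], rec["col_var"], cell)
        )
    return out


def _fmt_cell(c: CorrelationCell) -> str:
    return f"{c.rho:.2f} [{c.ci_low:.2f}, {c.ci_high:.2f}]{c.stars}"


def _fmt_mean(m: MeanWithCI) -> str:
    return f"{m.mean:.2f} [{m.ci_low:.2f}, {m.ci_high:.2f}]"


def _render_wide(cells: list[TableCell], row_order, mean_col=None) -> str:
    mcols = [m for m, _ in MEASURES]
    by_row: dict[str, dict[str, CorrelationCell]] = {}
    for tc in cells:
        by_row.setdefault(tc.row, {})[tc.col] = tc.cell
    header = [""]
    if mean_col is not None:
        header.append("Mean [95% CI]")
    header += [_LABELS[m] for m in mcols]
    lines = ["\t".join(header)]
    for rv, _ in row_order:
        if rv not in by_row:
            continue
        line = [_LABELS[rv]]
        if mean_col is not None:
            line.append(_fmt_mean(mean_col[rv]))
        line += [_fmt_cell(by_row[rv][m]) if m in by_row[rv] else "" for m in mcols]
        lines.append("\t".join(line))
    return "\n".join(lines)


def _render_table1(cells: list[TableCell]) -> str:
    mcols = [m for m, _ in MEASURES]
    by: dict[tuple, CorrelationCell] = {(tc.row, tc.col): tc.cell for tc in cells}
    lines = ["\t".join(["Measure"] + [_LABELS[m] for m in mcols[:-1]])]
    for i in range(1, len(mcols)):
        line = [_LABELS[mcols[i]]]
        for j in range(len(mcols) - 1):
            c = by.get((mcols[i], mcols[j]))
            line.append(_fmt_cell(c) if c else "")
        lines.append("\t".join(line))
    return "\n".join(lines)


_STAR_NOTE = "*p < 0.05, **p < 0.01, ***p < 0.001"


def report_text(report: StudyReport) -> str:
    """Human-readable rendering: 2-decimal rho, bracketed 95% CI, stars."""
    out = io.StringIO()
    w = out.write
    w(f"Participants: {report.n_participants}\n\n")
    w("Descriptives (mean [95% bootstrap CI]):\n")
    for k, m in report.descriptives.items():
        w(f"  {k}: {_fmt_mean(m)}\n")
    w("\nCategory frequencies:\n")
    for var, counts in report.band_frequencies.items():
        total = sum(counts.values())
        frag = ", ".join(
            f"{lbl}: {cnt} ({100 * cnt / total:.0f}%)"
            for lbl, cnt in sorted(counts.items())
        )
        w(f"  {var}: {frag}\n")
    w("\nMean element distances:\n")
    for k, m in report.mean_distances.items():
        w(f"  {_LABELS[k]}: {_fmt_mean(m)}\n")
    overl = "yes" if all(report.distance_overlap.values()) else "no"
    w(f"  all distance CIs overlap: {overl}\n")
    w("\nTable 1. Correlations between questionnaire scores\n")
    w(_render_table1(report.table1))
    w(f"\n{_STAR_NOTE}\n")
    w("\nTable 2. Element distances x questionnaire scores\n")
    w(_render_wide(report.table2, DISTANCE_ROWS, report.mean_distances))
    w(f"\n{_STAR_NOTE}\n")
    w("\nTable 3. Opposed-pole proportions x questionnaire scores\n")
    w(_render_wide(report.table3, OPPOSED_ROWS, report.mean_opposed))
    w(f"\n{_STAR_NOTE}\n")
    w("\nTable 4. Polarization x questionnaire scores\n")
    w(_render_wide(report.table4, POLARIZATION_ROWS, report.mean_polarization))
    w(f"\n{_STAR_NOTE}\n")
    return out.getvalue()


def _mean_dict(m: MeanWithCI) -> dict:
    return {
        "mean": m.mean,
        "ci_low": m.ci_low,
        "ci_high": m.ci_high,
        "n": m.n,
        "n_boot": m.n_boot,
        "seed": m.seed,
    }


def report_to_json(report: StudyReport) -> str:
    """Deterministic machine-readable serialization at full precision."""
    payload = {
        "n_participants": report.n_participants,
        "descriptives": {k: _mean_dict(v) for k, v in report.descriptives.items()},
        "band_frequencies": report.band_frequencies,
        "mean_distances": {k: _mean_dict(v) for k, v in report.mean_distances.items()},
        "distance_overlap": report.distance_overlap,
        "mean_opposed": {k: _mean_dict(v) for k, v in report.mean_opposed.items()},
        "mean_polarization": {
            k: _mean_dict(v) for k, v in report.mean_polarization.items()
        },
        "tables": {
            name: [_cell_dict(tc, name) for tc in cells]
            for name, cells in (
                ("table1", report.table1),
                ("table2", report.table2),
                ("table3", report.table3),
                ("table4", report.table4),
            )
        },
        "metadata": report.metadata,
    }
    return json.dumps(payload, indent=1, sort_keys=True)


_FORMATS = ("json", "csv", "txt")


def render_tables(report: StudyReport, outdir, formats=_FORMATS) -> list:
    """Write the report under ``outdir``: ``report.json`` (full precision),
    ``tables_long.csv`` (tidy cells; parses back to equal cells) and
    ``report.txt`` (human-readable tables)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; choose from {_FORMATS}")
        if fmt == "json":
            p = outdir / "report.json"
            p.write_text(report_to_json(report) + "\n", encoding="utf-8")
        elif fmt == "csv":
            p = outdir / "tables_long.csv"
            # %.17g guarantees float round-trip through the text format
            tables_long(report).to_csv(p, index=False, float_format="%.17g")
        else:
            p = outdir / "report.txt"
            p.write_text(report_text(report), encoding="utf-8")
        written.append(p)
    return written
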