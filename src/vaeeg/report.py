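"""Aggregation of significance decisions and published-table reconciliation.

The study's headline numbers are proportions of *non-significant*
comparisons — cells of the per-subject U-test table whose p-value is at
least 0.05, meaning the VR-simulated stimulation was statistically
indistinguishable from manual needling in that comparison.  This module
derives those proportions (overall, per day, per sex), counts subjects
whose every pairwise comparison is non-significant, computes the
band-vs-full-range decision similarity

    similarity = (AG + AL) / AN

(AG = subjects significant in both, AL = non-significant in both,
AN = all subjects), exports per-channel topography values, and
reconciles every recomputable printed aggregate against the packaged
verbatim transcriptions of the published tables.

Decisions are always taken on the numeric p-values with the ``p >= 0.05``
rule, never on the tables' bold markup: two cells of the pairwise table
are bolded at 0.03/0.04 in print, contradicting the stated bolding
convention, and only the numeric rule reproduces the cross-checkable
aggregates.  The printed bold masks are packaged alongside for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SubjectMeta
from .spectral import ChannelScores
from .stats import ComparisonTable, default_plan

__all__ = [
    "FixtureTable",
    "ConsistencyReport",
    "SimilarityResult",
    "load_fixture",
    "load_subjects",
    "decide",
    "consistency",
    "all_ns_subjects",
    "band_similarity",
    "table4_band_similarity",
    "topography_export",
    "reproduce_paper_aggregates",
]

ALPHA_DEFAULT = 0.05

#: Pairwise comparison columns, in published column order.
PAIRWISE_COLUMNS = default_plan().pairwise_labels
COMBINED_COLUMN = "MA_T vs VA_T"

#: Pairwise columns involving the first-day VA events (20 min post-MA)
#: and the second-day VA events (24 h post-MA).
DAY1_COLUMNS = [c for c in PAIRWISE_COLUMNS if c.endswith(("VA1", "VA2"))]
DAY2_COLUMNS = [c for c in PAIRWISE_COLUMNS if c.endswith(("VA3", "VA4"))]

BAND_COLUMNS = ["raw", "delta", "theta", "alpha", "beta", "gamma"]


@dataclass
class FixtureTable:
    """A verbatim transcription of one published table.

    ``cells`` maps ``(row_id, column)`` to the printed value (None when
    the table prints a dash), ``bold_mask`` to the printed bold flag
    where the table distinguishes bold cells.
    """

    name: str
    cells: dict[tuple[str, str], float | None]
    bold_mask: dict[tuple[str, str], bool]
    row_ids: list[str]
    columns: list[str]

    def column_values(self, column: str) -> dict[str, float | None]:
        return {r: self.cells[(r, column)] for r in self.row_ids}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.cells[(r, c)] for c in self.columns] for r in self.row_ids],
            index=self.row_ids, columns=self.columns,
        )


def _fixture_path(name: str) -> Path:
    return Path(resources.files("vaeeg") / "fixtures" / f"{name}.csv")


def load_fixture(name: str) -> FixtureTable:
    """Load a packaged table transcription (``table2``..``table4``)."""
    if name not in ("table2", "table3", "table4"):
        raise ValueError(f"unknown fixture table {name!r}")
    df = pd.read_csv(_fixture_path(name), dtype=str).set_index("id")
    value_cols = [c for c in df.columns if c != "sex"]
    cells: dict[tuple[str, str], float | None] = {}
    for row_id, row in df.iterrows():
        for col in value_cols:
            raw = row[col]
            cells[(row_id, col)] = None if raw.strip() == "-" else float(raw)
    bold_mask: dict[tuple[str, str], bool] = {}
    bold_path = _fixture_path(f"{name}_bold")
    if bold_path.exists():
        bold = pd.read_csv(bold_path, dtype=str).set_index("id")
        for row_id, row in bold.iterrows():
            for col in bold.columns:
                bold_mask[(row_id, col)] = row[col].strip() == "1"
    else:
        # the KS table bolds exactly the cells whose value is printed
        bold_mask = {key: v is not None for key, v in cells.items()}
    return FixtureTable(name, cells, bold_mask, list(df.index), value_cols)


def load_subjects() -> list[SubjectMeta]:
    """The 24 packaged subject records (12 male, 12 female)."""
    df = pd.read_csv(_fixture_path("table1"))
    return [
        SubjectMeta(r.id, r.sex, int(r.age), float(r.heart_rate),
                    float(r.body_temp), r.vr_history == "Y",
                    r.acu_history == "Y")
        for r in df.itertuples()
    ]


def decide(p: float, alpha: float = ALPHA_DEFAULT) -> str:
    """'ns' iff ``p >= alpha`` (the published bolding rule), else 'sig'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    return "ns" if p >= alpha else "sig"


@dataclass(frozen=True)
class ConsistencyReport:
    """Count of non-significant cells within one scope of the table."""

    scope: str
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion

    def __str__(self) -> str:
        return (f"{self.scope}: {self.numerator}/{self.denominator} "
                f"= {self.percent:.2f}%")


def _as_pvalue_frame(table: FixtureTable | ComparisonTable,
                     band: str = "raw") -> pd.DataFrame:
    if isinstance(table, FixtureTable):
        return table.frame()
    frame = table.to_frame(band).set_index("subject")
    return frame


def consistency(table: FixtureTable | ComparisonTable, scope: str,
                meta: Sequence[SubjectMeta] | None = None,
                alpha: float = ALPHA_DEFAULT) -> ConsistencyReport:
    """Proportion of non-significant comparisons within a scope.

    Scopes over the 9-comparison table: ``all-pairwise`` (the 8 pairwise
    columns), ``combined`` (the pooled MA_T vs VA_T column), ``day1`` /
    ``day2`` (pairwise columns whose VA event ran 20 min / 24 h after
    the manual sessions), ``male`` / ``female`` (pairwise columns,
    subjects filtered by the metadata sex — defaults to the packaged
    subject table).  ``band:<name>`` scopes a band-wise table to one of
    its columns.
    """
    frame = _as_pvalue_frame(table)
    if scope == "all-pairwise":
        sub = frame[PAIRWISE_COLUMNS]
    elif scope == "combined":
        sub = frame[[COMBINED_COLUMN]]
    elif scope == "day1":
        sub = frame[DAY1_COLUMNS]
    elif scope == "day2":
        sub = frame[DAY2_COLUMNS]
    elif scope in ("male", "female"):
        meta = meta if meta is not None else load_subjects()
        sex = "M" if scope == "male" else "F"
        ids = [m.id for m in meta if m.sex == sex]
        sub = frame.loc[[i for i in frame.index if i in ids],
                        PAIRWISE_COLUMNS]
    elif scope.startswith("band:"):
        band = scope.split(":", 1)[1]
        if band not in frame.columns:
            raise ValueError(f"no band column {band!r} in table")
        sub = frame[[band]]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    values = sub.to_numpy(dtype=float)
    present = ~np.isnan(values)
    numerator = int(((values >= alpha) & present).sum())
    return ConsistencyReport(scope, numerator, int(present.sum()))


def all_ns_subjects(table: FixtureTable | ComparisonTable,
                    alpha: float = ALPHA_DEFAULT) -> int:
    """Subjects for whom none of the 8 pairwise comparisons is significant."""
    frame = _as_pvalue_frame(table)[PAIRWISE_COLUMNS]
    values = frame.to_numpy(dtype=float)
    return int((values >= alpha).all(axis=1).sum())


@dataclass(frozen=True)
class SimilarityResult:
    """Agreement between band-wise and full-range decisions."""

    band: str
    AG: int          # significant in both
    AL: int          # non-significant in both
    AN: int          # all subjects

    @property
    def similarity(self) -> float:
        return (self.AG + self.AL) / self.AN

    @property
    def percent(self) -> float:
        return 100.0 * self.similarity


def band_similarity(raw_decisions: Mapping[str, str],
                    band_decisions: Mapping[str, str],
                    band: str = "band") -> SimilarityResult:
    """Fraction of subjects whose band decision matches the raw decision."""
    if set(raw_decisions) != set(band_decisions):
        raise ValueError("decision maps cover different subject sets")
    ag = sum(1 for s in raw_decisions
             if raw_decisions[s] == "sig" and band_decisions[s] == "sig")
    al = sum(1 for s in raw_decisions
             if raw_decisions[s] == "ns" and band_decisions[s] == "ns")
    return SimilarityResult(band, ag, al, len(raw_decisions))


def table4_band_similarity(table: FixtureTable, band: str,
                           alpha: float = ALPHA_DEFAULT) -> SimilarityResult:
    """Similarity of one band column against the raw column of the
    band-wise table."""
    raw = {s: decide(v, alpha) for s, v in table.column_values("raw").items()}
    bnd = {s: decide(v, alpha) for s, v in table.column_values(band).items()}
    return band_similarity(raw, bnd, band)


def topography_export(scores: ChannelScores, montage: Sequence[str],
                      path: str | Path | None = None,
                      render: str | Path | None = None) -> pd.DataFrame:
    """Per-channel topography values ``(channel, S_m, S_m_dB)``.

    Writes a CSV when ``path`` is given and, when ``render`` is given, a
    generic interpolated scalp map at the 10-20 positions.
    """
    missing = [ch for ch in montage if ch not in scores.S_m]
    if missing:
        raise ValueError(f"scores missing channels: {missing}")
    db = scores.S_m_dB
    frame = pd.DataFrame({
        "channel": list(montage),
        "S_m": [scores.S_m[ch] for ch in montage],
        "S_m_dB": [db[ch] for ch in montage],
    })
    if path is not None:
        frame.to_csv(path, index=False)
    if render is not None:
        _render_scalp_map(frame, Path(render))
    return frame


#: Approximate 2-D head-circle positions of the 16 montage electrodes.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.55), "F4": (0.43, 0.55),
    "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.43, -0.55), "P4": (0.43, -0.55),
    "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def _render_scalp_map(frame: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    pts = np.array([_POSITIONS[ch] for ch in frame["channel"]])
    vals = frame["S_m_dB"].to_numpy()
    grid_x, grid_y = np.mgrid[-1.1:1.1:120j, -1.1:1.1:120j]
    interp = griddata(pts, vals, (grid_x, grid_y), method="cubic")
    mask = grid_x ** 2 + grid_y ** 2 > 1.1 ** 2
    interp[mask] = np.nan
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.pcolormesh(grid_x, grid_y, interp, shading="auto")
    ax.add_patch(plt.Circle((0, 0), 1.1, fill=False, lw=1.5))
    ax.scatter(pts[:, 0], pts[:, 1], s=8, c="k")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.colorbar(im, ax=ax, label="S_m (dB)")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


@dataclass(frozen=True)
class AggregateCheck:
    name: str
    printed: float
    computed: float
    passed: bool
    note: str = ""
    informational: bool = False      # known discrepancy, not a failure


def reproduce_paper_aggregates(
        fixtures: Mapping[str, FixtureTable] | None = None,
) -> list[AggregateCheck]:
    """Recompute every cross-checkable printed aggregate from fixtures.

    Returns one check per aggregate, each comparing the recomputed count
    or percentage to the printed value.  Known non-recomputable printed
    claims (the '21/24 subjects with more than 50% consistent events'
    figure and the alpha/beta/gamma similarity footer values) are
    reported as informational discrepancies rather than failures.

    An empty fixture mapping yields an empty report.
    """
    if fixtures is None:
        fixtures = {name: load_fixture(name)
                    for name in ("table2", "table3", "table4")}
    if not fixtures:
        return []
    checks: list[AggregateCheck] = []

    def add(name: str, printed: float, computed: float, note: str = "",
            informational: bool = False) -> None:
        passed = informational or bool(abs(printed - computed) < 0.005)
        checks.append(AggregateCheck(name, printed, round(computed, 2),
                                     passed, note, informational))

    t2 = fixtures.get("table2")
    if t2 is not None:
        normal = sum(1 for v in t2.cells.values()
                     if v is not None and v >= ALPHA_DEFAULT)
        add("ks_normal_events", 10, normal,
            "events passing the normality screen")

    t3 = fixtures.get("table3")
    if t3 is not None:
        add("pairwise_ns_percent", 63.54,
            consistency(t3, "all-pairwise").percent,
            "share of pairwise comparisons with p >= 0.05")
        add("combined_ns_percent", 66.67,
            consistency(t3, "combined").percent,
            "share of subjects ns in the pooled MA_T vs VA_T test")
        add("all_ns_subject_percent", 29.17,
            100.0 * all_ns_subjects(t3) / len(t3.row_ids),
            "subjects with every pairwise comparison ns")
        add("day1_ns_percent", 59.375, consistency(t3, "day1").percent,
            "VA 20 min after MA (printed as 59.36%, a rounding slip "
            "for 57/96)")
        add("day2_ns_percent", 67.71, consistency(t3, "day2").percent,
            "VA 24 h after MA")
        add("male_ns_percent", 60.42, consistency(t3, "male").percent,
            "printed as 60.41%, truncation of 58/96")
        add("female_ns_percent", 66.67, consistency(t3, "female").percent)
        add("majority_consistent_subjects_percent", 87.50, float("nan"),
            "printed claim '21/24 subjects with >50% consistent events' "
            "is not recomputable from the pairwise table under any "
            "natural threshold", informational=True)

    t4 = fixtures.get("table4")
    if t4 is not None:
        add("delta_ns_count", 17,
            consistency(t4, "band:delta").numerator,
            "delta-band ns subjects")
        add("theta_ns_count", 15,
            consistency(t4, "band:theta").numerator,
            "theta-band ns subjects")
        add("delta_similarity_percent", 79.17,
            table4_band_similarity(t4, "delta").percent)
        add("theta_similarity_percent", 79.17,
            table4_band_similarity(t4, "theta").percent)
        for band, printed in (("alpha", 70.83), ("beta", 54.17),
                              ("gamma", 62.50)):
            add(f"{band}_similarity_percent", printed,
                table4_band_similarity(t4, band).percent,
                "printed footer value does not re-derive from the "
                "table's own decision columns; known discrepancy",
                informational=True)
    return checks
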