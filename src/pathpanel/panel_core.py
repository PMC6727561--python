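"""Domain types for counts-based expression panels, plus TSV readers/writers.

A *panel* (codeset) is the fixed set of hybridization probes on a digital
counting assay: endogenous query genes, housekeeping genes used for content
normalization, a ladder of positive-control spike-ins with known nominal
concentrations (fM), and negative controls that measure background.

A *counts experiment* is a lanes x probes matrix of non-negative integer
molecule counts plus per-lane metadata (sample id and a group label).

File dialect: tab-separated UTF-8; lines starting with ``#`` are comments.
Panel files have columns ``name``, ``class``, ``nominal_conc``; counts files
have ``sample_id``, ``group`` and then one column per panel probe.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeClass",
    "Probe",
    "Panel",
    "CountsExperiment",
    "PanelFormatError",
    "load_panel",
    "load_counts",
    "write_panel",
    "write_counts",
    "write_table",
]


class PanelFormatError(ValueError):
    """Raised when a panel/counts file violates the dialect or its invariants."""


class ProbeClass(str, enum.Enum):
    ENDOGENOUS = "endogenous"
    HOUSEKEEPING = "housekeeping"
    POSITIVE_CTRL = "positive_ctrl"
    NEGATIVE_CTRL = "negative_ctrl"


@dataclass(frozen=True)
class Probe:
    """One probe on the panel.

    ``nominal_conc`` (fM) is required for positive controls and absent
    otherwise.
    """

    name: str
    probe_class: ProbeClass
    nominal_conc: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelFormatError("probe name must be nonempty")
        if self.probe_class is ProbeClass.POSITIVE_CTRL:
            if self.nominal_conc is None:
                raise PanelFormatError(
                    f"positive control {self.name!r} is missing nominal_conc"
                )
            if not self.nominal_conc > 0:
                raise PanelFormatError(
                    f"positive control {self.name!r} must have nominal_conc > 0"
                )
        elif self.nominal_conc is not None:
            raise PanelFormatError(
                f"probe {self.name!r} of class {self.probe_class.value} "
                "must not carry nominal_conc"
            )


@dataclass
class Panel:
    """Ordered probe catalog defining the assay."""

    probes: list[Probe]
    name: str = "panel"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dups: list[str] = []
        for p in self.probes:
            if p.name in seen:
                dups.append(p.name)
            seen.add(p.name)
        if dups:
            raise PanelFormatError(f"duplicate probe names: {sorted(set(dups))}")

    def _names(self, cls: ProbeClass) -> list[str]:
        return [p.name for p in self.probes if p.probe_class is cls]

    @property
    def probe_names(self) -> list[str]:
        return [p.name for p in self.probes]

    @property
    def endogenous(self) -> list[str]:
        return self._names(ProbeClass.ENDOGENOUS)

    @property
    def housekeeping(self) -> list[str]:
        return self._names(ProbeClass.HOUSEKEEPING)

    @property
    def positive_ctrl(self) -> list[str]:
        return self._names(ProbeClass.POSITIVE_CTRL)

    @property
    def negative_ctrl(self) -> list[str]:
        return self._names(ProbeClass.NEGATIVE_CTRL)

    @property
    def n_genes(self) -> int:
        """Endogenous plus housekeeping probes (the 'gene' content)."""
        return len(self.endogenous) + len(self.housekeeping)

    @property
    def positive_concs(self) -> pd.Series:
        return pd.Series(
            {p.name: p.nominal_conc for p in self.probes
             if p.probe_class is ProbeClass.POSITIVE_CTRL},
            dtype=float,
        )

    def require_controls(self) -> None:
        """Check the control content needed for normalization and DE."""
        if len(self.housekeeping) < 1:
            raise PanelFormatError("panel needs >=1 housekeeping probe")
        pos = self.positive_concs
        if len(pos) < 2:
            raise PanelFormatError("panel needs >=2 positive-control probes")
        if pos.nunique() != len(pos):
            raise PanelFormatError(
                "positive-control nominal concentrations must be distinct"
            )
        if len(self.negative_ctrl) < 1:
            raise PanelFormatError("panel needs >=1 negative-control probe")

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class CountsExperiment:
    """Lanes x probes integer counts with lane metadata.

    ``counts`` is a DataFrame indexed by sample_id with columns in panel probe
    order; ``lanes`` holds sample_id, group and free-form attributes.
    """

    panel: Panel
    lanes: pd.DataFrame  # columns: sample_id, group, plus attributes
    counts: pd.DataFrame  # index: sample_id; columns: panel probe order

    def __post_init__(self) -> None:
        ids = self.lanes["sample_id"]
        if ids.duplicated().any():
            raise PanelFormatError(
                f"duplicate sample ids: {sorted(ids[ids.duplicated()])}"
            )
        if list(self.counts.columns) != self.panel.probe_names:
            missing = set(self.panel.probe_names) - set(self.counts.columns)
            if missing:
                raise PanelFormatError(f"missing probe columns: {sorted(missing)}")
            self.counts = self.counts[self.panel.probe_names]
        if list(self.counts.index) != list(ids):
            raise PanelFormatError("counts index must equal lane sample_ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            flo = np.asarray(arr, dtype=float)
            if not np.all(flo == np.round(flo)):
                bad = np.argwhere(flo != np.round(flo))[0]
                raise PanelFormatError(
                    "non-integer count at lane "
                    f"{self.counts.index[bad[0]]!r}, probe "
                    f"{self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise PanelFormatError(
                f"negative count at lane {self.counts.index[bad[0]]!r}, "
                f"probe {self.counts.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lanes["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return self.lanes.set_index("sample_id")["group"]

    def subset_lanes(self, sample_ids: Sequence[str]) -> "CountsExperiment":
        keep = self.lanes["sample_id"].isin(set(sample_ids))
        return CountsExperiment(
            panel=self.panel,
            lanes=self.lanes[keep].reset_index(drop=True),
            counts=self.counts.loc[self.lanes.loc[keep, "sample_id"]],
        )


# ---------------------------------------------------------------------------
# Readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, encoding="utf-8")


def load_panel(path: str | Path) -> Panel:
    """Read a panel definition TSV (columns: name, class, nominal_conc)."""
    df = _read_tsv(path)
    required = {"name", "class"}
    if not required <= set(df.columns):
        raise PanelFormatError(
            f"panel file must have columns {sorted(required)}; got {list(df.columns)}"
        )
    probes: list[Probe] = []
    for _, row in df.iterrows():
        token = row["class"].strip().lower()
        try:
            cls = ProbeClass(token)
        except ValueError:
            raise PanelFormatError(f"unknown probe class {row['class']!r}") from None
        conc_raw = row.get("nominal_conc", "")
        conc = None
        if conc_raw not in ("", "NA", "."):
            conc = float(conc_raw)
        if cls is ProbeClass.POSITIVE_CTRL and conc is None:
            raise PanelFormatError(
                f"positive control {row['name']!r} is missing nominal_conc"
            )
        if cls is not ProbeClass.POSITIVE_CTRL:
            conc = None
        probes.append(Probe(name=row["name"], probe_class=cls, nominal_conc=conc))
    return Panel(probes=probes, name=str(Path(path).stem))


def write_panel(panel: Panel, path: str | Path,
                comments: Iterable[str] = ()) -> None:
    rows = [
        {
            "name": p.name,
            "class": p.probe_class.value,
            "nominal_conc": "" if p.nominal_conc is None else repr(p.nominal_conc),
        }
        for p in panel.probes
    ]
    write_table(rows, path, comments=comments)


def load_counts(path: str | Path, panel: Panel) -> CountsExperiment:
    """Read a counts TSV (sample_id, group, one column per panel probe).

    Probe columns may appear in any order; they are reindexed to panel order.
    """
    df = _read_tsv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise PanelFormatError(f"counts file missing column {col!r}")
    probe_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    missing = [p for p in panel.probe_names if p not in probe_cols]
    if missing:
        raise PanelFormatError(f"missing probe columns: {missing}")
    counts = df[panel.probe_names].copy()
    for col in panel.probe_names:
        vals = pd.to_numeric(counts[col], errors="raise")
        flo = vals.astype(float)
        if not np.all(flo == np.round(flo)):
            j = int(np.argmax(flo != np.round(flo)))
            raise PanelFormatError(
                f"non-integer count {counts[col].iloc[j]!r} at lane "
                f"{df['sample_id'].iloc[j]!r}, probe {col!r}"
            )
        counts[col] = flo.astype(np.int64)
    counts.index = pd.Index(df["sample_id"], name="sample_id")
    lanes = df[["sample_id", "group"]].reset_index(drop=True)
    return CountsExperiment(panel=panel, lanes=lanes, counts=counts)


def write_counts(exp: CountsExperiment, path: str | Path,
                 comments: Iterable[str] = ()) -> None:
    rows = []
    for sid, group in zip(exp.lanes["sample_id"], exp.lanes["group"]):
        row: dict[str, object] = {"sample_id": sid, "group": group}
        row.update(exp.counts.loc[sid].to_dict())
        rows.append(row)
    write_table(rows, path, comments=comments)


def _format_cell(v: object) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return format(float(v), ".9g")
    return str(v)


def write_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                header: Sequence[str] | None = None,
                comments: Iterable[str] = ()) -> None:
    """Write keyed records as TSV; all records must share one key set.

    Floats are written with 9 significant digits so a read-back reproduces
    them to formatting precision. An empty record list writes the header only
    (pass ``header`` to name the columns, else the file is just comments).
    """
    rows = list(rows)
    if rows:
        keys = list(rows[0].keys())
        for r in rows[1:]:
            if list(r.keys()) != keys:
                raise ValueError("heterogeneous record keys in write_table")
        if header is not None and list(header) != keys:
            raise ValueError("header does not match record keys")
    else:
        keys = list(header) if header is not None else []
    buf = io.StringIO()
    for c in comments:
        buf.write(f"# {c}\n")
    if keys:
        buf.write("\t".join(keys) + "\n")
    for r in rows:
        buf.write("\t".join(_format_cell(r[k]) for k in keys) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`, inferring dtypes."""
    return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
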