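"""Reading, writing and labeling of drug-combination synergy data.

A study is a collection of triplets ``(drug_i, drug_j, cell_line)`` with one
or more continuous synergy scores (Loewe additivity, Bliss independence, ZIP,
HSA).  Continuous scores are mapped to three interaction classes —
synergistic, additive, antagonistic — by published per-metric cut-offs, and
to a binary view (synergistic = positive) for classification metrics.

External formats are plain delimited text (comma or tab, auto-detected):

* synergy table: ``drug_i,drug_j,cell_line,loewe[,bliss,zip,hsa]``
* drug table: ``drug_id,smiles``
* fingerprints: ``drug_id`` index column + numeric feature columns
* expression: ``cell_line`` index column + numeric gene columns
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYNERGISTIC = "synergistic"
ADDITIVE = "additive"
ANTAGONISTIC = "antagonistic"
CLASSES = (SYNERGISTIC, ADDITIVE, ANTAGONISTIC)

METRICS = ("loewe", "bliss", "zip", "hsa")


@dataclass(frozen=True)
class ThresholdScheme:
    """Per-metric decision rule: synergistic if ``score >= synergy_min``,
    antagonistic if ``score <= additive_low``, additive otherwise.

    ``additive_high`` records the upper end of the additive interval; after
    closing the published gap in the ZIP rule it coincides with
    ``synergy_min`` for every metric, making the rule a total partition of the
    real line.
    """

    metric: str
    additive_low: float
    additive_high: float
    synergy_min: float

    def __post_init__(self):
        if not (self.additive_low <= self.additive_high <= self.synergy_min):
            raise ValueError(
                f"invalid scheme for {self.metric}: need "
                f"additive_low <= additive_high <= synergy_min"
            )

    def label(self, score: float) -> str:
        if not np.isfinite(score):
            raise ValueError(f"cannot label non-finite score {score!r}")
        if score >= self.synergy_min:
            return SYNERGISTIC
        if score <= self.additive_low:
            return ANTAGONISTIC
        return ADDITIVE


#: Published class cut-offs per synergy metric.  The ZIP additive interval is
#: extended up to the synergy cut (3.87) so the three classes partition the
#: real line; the published additive upper end (3.68) left a gap.
SCHEMES: dict[str, ThresholdScheme] = {
    "loewe": ThresholdScheme("loewe", 0.0, 30.0, 30.0),
    "bliss": ThresholdScheme("bliss", -3.37, 3.68, 3.68),
    "zip": ThresholdScheme("zip", -3.37, 3.87, 3.87),
    "hsa": ThresholdScheme("hsa", -4.48, 2.64, 2.64),
}


def label_interaction(score: float, scheme: ThresholdScheme | str) -> str:
    """Classify a continuous synergy score under a threshold scheme."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    return scheme.label(score)


def binarize_labels(labels):
    """Collapse 3-class labels to the binary view used for classification:
    synergistic is the positive class, additive and antagonistic the negative.
    """

    def _one(lab: str) -> str:
        if lab == SYNERGISTIC:
            return "positive"
        if lab in (ADDITIVE, ANTAGONISTIC):
            return "negative"
        raise ValueError(f"unknown interaction class {lab!r}")

    if isinstance(labels, str):
        return _one(labels)
    return [_one(lab) for lab in labels]


@dataclass
class SynergyRecord:
    """One measured drug pair in one cell line."""

    drug_i: str
    drug_j: str
    cell_line: str
    scores: dict[str, float]
    _labels: dict[str, str] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.drug_i == self.drug_j:
            raise ValueError(f"self-pair {self.drug_i!r} in {self.cell_line!r}")

    def label(self, metric: str) -> str:
        """Interaction class for ``metric`` (cached, recomputable)."""
        if metric not in self._labels:
            self._labels[metric] = label_interaction(self.scores[metric], metric)
        return self._labels[metric]


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_synergy_table(path, aggregate: str = "mean") -> list[SynergyRecord]:
    """Read a synergy table into canonical records.

    Pairs are unordered: each record is stored with ``drug_i < drug_j``
    (lexicographically; datasets re-canonicalize by drug index).  Replicate
    measurements of the same unordered ``(i, j, r)`` triplet are reduced by
    ``aggregate`` (``mean`` | ``median`` | ``first`` | ``error``).
    """
    if aggregate not in ("mean", "median", "first", "error"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"drug_i", "drug_j", "cell_line"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"synergy table {path}: missing required columns {sorted(missing)}")
    metric_cols = [c for c in df.columns if c in METRICS]
    if not metric_cols:
        raise ValueError(f"synergy table {path}: no synergy metric column among {METRICS}")

    parsed: dict[tuple[str, str, str], list[dict[str, float]]] = {}
    order: list[tuple[str, str, str]] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        a, b = str(rec["drug_i"]), str(rec["drug_j"])
        if a == b:
            raise ValueError(f"{path}:{row_no}: self-pair {a!r}")
        i, j = (a, b) if a <= b else (b, a)
        scores = {}
        for m in metric_cols:
            raw = rec[m]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            try:
                scores[m] = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{row_no}: non-numeric {m} score {raw!r}"
                ) from exc
        key = (i, j, str(rec["cell_line"]))
        if key not in parsed:
            parsed[key] = []
            order.append(key)
        parsed[key].append(scores)

    records = []
    for key in order:
        reps = parsed[key]
        if len(reps) > 1 and aggregate == "error":
            raise ValueError(f"duplicate triplet {key} with aggregate='error'")
        merged: dict[str, float] = {}
        for m in metric_cols:
            vals = [r[m] for r in reps if m in r]
            if not vals:
                continue
            if aggregate == "first" or len(vals) == 1:
                merged[m] = vals[0]
            elif aggregate == "median":
                merged[m] = float(np.median(vals))
            else:
                merged[m] = float(np.mean(vals))
        records.append(SynergyRecord(key[0], key[1], key[2], merged))
    return records


def write_synergy_table(records: list[SynergyRecord], path) -> None:
    """Write records in the canonical delimited format (comma, UTF-8)."""
    metrics = [m for m in METRICS if any(m in r.scores for r in records)]
    rows = [
        {"drug_i": r.drug_i, "drug_j": r.drug_j, "cell_line": r.cell_line,
         **{m: r.scores.get(m, np.nan) for m in metrics}}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["drug_i", "drug_j", "cell_line", *metrics])
    df.to_csv(path, index=False)


def read_drug_table(path) -> dict[str, str]:
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if not {"drug_id", "smiles"} <= set(df.columns):
        raise ValueError(f"drug table {path}: needs columns drug_id, smiles")
    return dict(zip(df["drug_id"], df["smiles"]))


def read_matrix(path, index_name: str) -> tuple[list[str], np.ndarray]:
    """Read a delimited numeric matrix with a leading index column."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.columns[0] != index_name:
        raise ValueError(f"{path}: first column must be {index_name!r}, got {df.columns[0]!r}")
    ids = [str(v) for v in df.iloc[:, 0]]
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return ids, values


def write_matrix(ids: list[str], values: np.ndarray, index_name: str, path) -> None:
    df = pd.DataFrame(values, columns=[f"f{k}" for k in range(values.shape[1])])
    df.insert(0, index_name, ids)
    df.to_csv(path, index=False)


@dataclass
class SynergyDataset:
    """Canonical in-memory form of one study.

    ``drugs`` fixes the drug ordering (row order of ``fingerprints``), and
    ``cell_lines`` the cell-line ordering (row order of ``expression``).
    """

    records: list[SynergyRecord]
    drugs: list[str]
    smiles: dict[str, str]
    cell_lines: list[str]
    fingerprints: np.ndarray | None = None
    expression: np.ndarray | None = None

    def __post_init__(self):
        self._drug_index = {d: k for k, d in enumerate(self.drugs)}
        self._cell_index = {c: k for k, c in enumerate(self.cell_lines)}
        if len(self._drug_index) != len(self.drugs):
            raise ValueError("duplicate drug identifiers")
        if self.fingerprints is not None and self.fingerprints.shape[0] != len(self.drugs):
            raise ValueError("fingerprint row count must equal drug count")
        if self.expression is not None and self.expression.shape[0] != len(self.cell_lines):
            raise ValueError("expression row count must equal cell-line count")
        canon, seen = [], set()
        for r in self.records:
            if r.drug_i not in self._drug_index or r.drug_j not in self._drug_index:
                raise ValueError(f"record references unknown drug: {r.drug_i!r}/{r.drug_j!r}")
            if r.cell_line not in self._cell_index:
                raise ValueError(f"record references unknown cell line {r.cell_line!r}")
            if self._drug_index[r.drug_i] > self._drug_index[r.drug_j]:
                r = SynergyRecord(r.drug_j, r.drug_i, r.cell_line, r.scores)
            key = (r.drug_i, r.drug_j, r.cell_line)
            if key in seen:
                raise ValueError(f"duplicate triplet {key} after canonicalization")
            seen.add(key)
            canon.append(r)
        self.records = canon

    # -- index helpers ---------------------------------------------------------
    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)

    def drug_index(self, drug: str) -> int:
        return self._drug_index[drug]

    def cell_index(self, cell: str) -> int:
        return self._cell_index[cell]

    def triplet_indices(self, metric: str | None = None) -> np.ndarray:
        """(n_records, 3) integer array of (i, j, r) indices; when ``metric``
        is given, restricted to records carrying that score."""
        rows = [
            (self._drug_index[r.drug_i], self._drug_index[r.drug_j],
             self._cell_index[r.cell_line])
            for r in self.records
            if metric is None or metric in r.scores
        ]
        return np.asarray(rows, dtype=int).reshape(-1, 3)

    def scores(self, metric: str) -> np.ndarray:
        return np.asarray([r.scores[metric] for r in self.records if metric in r.scores])

    def labels(self, metric: str) -> list[str]:
        return [r.label(metric) for r in self.records if metric in r.scores]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SynergyDataset):
            return NotImplemented

        def arr_eq(a, b):
            return (a is None) == (b is None) and (a is None or np.allclose(a, b))

        return (
            self.records == other.records
            and self.drugs == other.drugs
            and self.smiles == other.smiles
            and self.cell_lines == other.cell_lines
            and arr_eq(self.fingerprints, other.fingerprints)
            and arr_eq(self.expression, other.expression)
        )


def load_dataset(
    synergy_path,
    drugs_path,
    expression_path,
    fingerprints_path=None,
    aggregate: str = "mean",
) -> SynergyDataset:
    """Assemble a :class:`SynergyDataset` from the four standard input files."""
    records = read_synergy_table(synergy_path, aggregate=aggregate)
    smiles = read_drug_table(drugs_path)
    cell_ids, expression = read_matrix(expression_path, "cell_line")
    drugs = sorted(smiles)
    fingerprints = None
    if fingerprints_path is not None:
        fp_ids, fp = read_matrix(fingerprints_path, "drug_id")
        order = {d: k for k, d in enumerate(fp_ids)}
        fingerprints = fp[[order[d] for d in drugs]]
    return SynergyDataset(records, drugs, smiles, cell_ids, fingerprints, expression)
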