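"""Sequence- and metric-level design filter cascade.

After docking and sequence design, candidate nanoparticle designs are culled
by a cascade of independent predicates:

* **alanine party** — reject sequences containing four or more consecutive
  alanines (a known ProteinMPNN failure mode); an annotated motif span is
  exempt, since scaffolded motif placeholders are sequence-variable.
* **degreaser** — reject predicted cryptic transmembrane insertion,
  ddG_ins,pred < 2.6 required (an externally computed pass-through metric).
* **pLDDT / pAE** — structure-prediction confidence, pLDDT > 90 and pAE < 5.
* **ddG** — interface energy of the assembled nanoparticle, ddG < -10
  (Rosetta energy units).

All thresholds are taken strictly as printed; "cutoff of -10" is read as
ddG < -10. Metrics this module does not compute (pLDDT, pAE, ddG,
ddG_ins,pred) are pass-through inputs: a record missing a metric is marked
"skipped" for that stage and is never counted as passing it. The stages are
independent predicates, so the final survivor set does not depend on stage
order. A visual-inspection stage is representable only as a manual exclusion
list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import SequenceError
from .blocks import AA_ALPHABET

_AA_SET = frozenset(AA_ALPHABET)

PASS, FAIL, SKIPPED = "pass", "fail", "skipped"

#: canonical stage names in default application order
DEFAULT_STAGE_ORDER = ("ala_party", "degreaser", "plddt", "pae", "ddg", "manual")


@dataclass
class DesignRecord:
    design_id: str
    sequence: str
    motif_span: tuple[int, int] | None = None  # inclusive, 1-based
    plddt: float | None = None
    pae: float | None = None
    ddg: float | None = None
    ddg_ins_pred: float | None = None
    stage_flags: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CascadeConfig:
    """Filter thresholds (strict inequalities, as printed) and stage order."""

    ala_party_min_run: int = 4
    plddt_min: float = 90.0
    pae_max: float = 5.0
    ddg_max: float = -10.0
    ddg_ins_max: float = 2.6
    stage_order: tuple = DEFAULT_STAGE_ORDER
    manual_exclude: frozenset = frozenset()

    def __post_init__(self):
        unknown = set(self.stage_order) - set(DEFAULT_STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown cascade stages {sorted(unknown)}")


def alanine_party_runs(
    sequence: str,
    min_run: int = 4,
    motif_span: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive alanines of length >= ``min_run``.

    Returns (start, length) pairs with 1-based inclusive starts. Runs lying
    entirely inside ``motif_span`` are excluded (placeholder motif sequence is
    not a design liability). Characters outside the 20-letter alphabet are
    rejected with their position.
    """
    for i, ch in enumerate(sequence):
        if ch not in _AA_SET:
            raise SequenceError(
                f"invalid amino-acid character {ch!r} at position {i + 1}"
            )
    runs = []
    i = 0
    n = len(sequence)
    while i < n:
        if sequence[i] == "A":
            j = i
            while j < n and sequence[j] == "A":
                j += 1
            if j - i >= min_run:
                runs.append((i + 1, j - i))
            i = j
        else:
            i += 1
    if motif_span is not None:
        lo, hi = motif_span
        runs = [(s, ln) for s, ln in runs if not (s >= lo and s + ln - 1 <= hi)]
    return runs


def _stage_flag(record: DesignRecord, stage: str, config: CascadeConfig) -> str:
    if stage == "ala_party":
        runs = alanine_party_runs(
            record.sequence, config.ala_party_min_run, record.motif_span
        )
        return FAIL if runs else PASS
    if stage == "degreaser":
        if record.ddg_ins_pred is None:
            return SKIPPED
        return PASS if record.ddg_ins_pred < config.ddg_ins_max else FAIL
    if stage == "plddt":
        if record.plddt is None:
            return SKIPPED
        return PASS if record.plddt > config.plddt_min else FAIL
    if stage == "pae":
        if record.pae is None:
            return SKIPPED
        return PASS if record.pae < config.pae_max else FAIL
    if stage == "ddg":
        if record.ddg is None:
            return SKIPPED
        return PASS if record.ddg < config.ddg_max else FAIL
    if stage == "manual":
        return FAIL if record.design_id in config.manual_exclude else PASS
    raise ValueError(f"unknown stage {stage!r}")


def apply_cascade(
    records: list[DesignRecord], config: CascadeConfig | None = None
) -> tuple[list[DesignRecord], pd.DataFrame]:
    """Run the filter cascade and report per-stage attrition.

    Every record is annotated with a flag per stage. A record survives only
    if it passes every configured stage; a "skipped" stage (absent metric)
    removes the record from the survivor pool but is tallied separately from
    failures. The attrition table lists, per stage in configured order, the
    number of records entering, failing, skipped, and surviving. Because the
    stages are independent predicates, the survivor set is invariant under
    stage reordering.
    """
    config = config or CascadeConfig()
    for rec in records:
        rec.stage_flags = {
            stage: _stage_flag(rec, stage, config) for stage in config.stage_order
        }
    rows = []
    alive = list(records)
    for stage in config.stage_order:
        entering = len(alive)
        failed = sum(1 for r in alive if r.stage_flags[stage] == FAIL)
        skipped = sum(1 for r in alive if r.stage_flags[stage] == SKIPPED)
        alive = [r for r in alive if r.stage_flags[stage] == PASS]
        rows.append(
            {
                "stage": stage,
                "input": entering,
                "failed": failed,
                "skipped": skipped,
                "surviving": len(alive),
            }
        )
    return alive, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# record I/O (TSV and JSON lines)

_METRIC_FIELDS = ("plddt", "pae", "ddg", "ddg_ins_pred")


def records_to_frame(records: list[DesignRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"design_id": r.design_id, "sequence": r.sequence}
        row["motif_start"] = r.motif_span[0] if r.motif_span else None
        row["motif_end"] = r.motif_span[1] if r.motif_span else None
        for f in _METRIC_FIELDS:
            row[f] = getattr(r, f)
        for stage, flag in r.stage_flags.items():
            row[f"stage_{stage}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def _record_from_mapping(row: dict) -> DesignRecord:
    span = None
    ms, me = row.get("motif_start"), row.get("motif_end")
    if ms is not None and me is not None and not pd.isna(ms) and not pd.isna(me):
        span = (int(ms), int(me))
    kwargs = {}
    for f in _METRIC_FIELDS:
        v = row.get(f)
        kwargs[f] = None if v is None or (isinstance(v, float) and pd.isna(v)) else float(v)
    return DesignRecord(
        design_id=str(row["design_id"]),
        sequence=str(row["sequence"]),
        motif_span=span,
        **kwargs,
    )


def read_records(path) -> list[DesignRecord]:
    """Read design records from TSV or JSON-lines (by extension)."""
    path = str(path)
    if path.endswith((".json", ".jsonl")):
        with open(path) as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
    else:
        rows = pd.read_csv(path, sep="\t").to_dict(orient="records")
    return [_record_from_mapping(row) for row in rows]


def write_records(records: list[DesignRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
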