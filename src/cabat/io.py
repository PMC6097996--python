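"""File formats and run configuration.

Plain-text formats throughout: item banks and response matrices as UTF-8
comma-separated CSV with a header row, beat annotations and tap takes as
JSON, session logs as JSON lines (one event per line), audio as WAV.
Loaders enforce the type invariants and report the first violation with
row context through :class:`FormatError`, which carries a machine-readable
``code``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adaptive import SessionResult
from .calibration import ResponseMatrix
from .estimation import EstimateResult
from .item_bank import (
    DifficultyCoefficients,
    ItemBank,
    ItemSpec,
    PUBLISHED_COEFFICIENTS,
    predict_difficulty,
)
from .model_core import ScoredResponse
from .stimulus import BeatAnnotation, TapTake, Waveform

__all__ = [
    "FormatError",
    "RunConfig",
    "write_bank",
    "read_bank",
    "write_matrix",
    "read_matrix",
    "write_session_log",
    "read_session_log",
    "write_annotation",
    "read_annotation",
    "write_tap_takes",
    "read_tap_takes",
    "write_wav",
]

BANK_COLUMNS = ["item_id", "track_id", "offset", "accuracy", "direction", "order", "difficulty"]


class FormatError(ValueError):
    """A malformed input file; ``code`` is machine-readable."""

    def __init__(self, code: str, message: str):
        super().__init__(f"[{code}] {message}")
        self.code = code


@dataclass
class RunConfig:
    """Top-level configuration with published-model defaults."""

    seed: int = 0
    test_length: int = 25
    first_item_difficulty_target: float = -0.01
    intercept: float = PUBLISHED_COEFFICIENTS.intercept
    accuracy_effect: float = PUBLISHED_COEFFICIENTS.accuracy_effect
    direction_effect: float = PUBLISHED_COEFFICIENTS.direction_effect
    discrimination: float = PUBLISHED_COEFFICIENTS.discrimination
    sample_rate: int = 44_100
    paths: dict = field(default_factory=dict)
    verbosity: str = "info"

    def coefficients(self) -> DifficultyCoefficients:
        return DifficultyCoefficients(
            intercept=self.intercept,
            accuracy_effect=self.accuracy_effect,
            direction_effect=self.direction_effect,
            discrimination=self.discrimination,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError("unknown-config-key", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# -- item banks ---------------------------------------------------------------

def write_bank(bank: ItemBank, path: str | Path) -> None:
    path = Path(path)
    c = bank.coefficients
    header = (
        f"# coefficients: intercept={c.intercept!r} accuracy_effect={c.accuracy_effect!r} "
        f"direction_effect={c.direction_effect!r} discrimination={c.discrimination!r}\n"
    )
    rows = pd.DataFrame(
        {
            "item_id": [it.item_id for it in bank.items],
            "track_id": [it.track_id for it in bank.items],
            "offset": [f"{it.offset:.12g}" for it in bank.items],
            "accuracy": [f"{it.accuracy:.12g}" for it in bank.items],
            "direction": [it.direction for it in bank.items],
            "order": [it.order for it in bank.items],
            "difficulty": [f"{it.difficulty:.9g}" for it in bank.items],
        }
    )
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header)
        rows.to_csv(fh, index=False)


def _parse_bank_header(line: str) -> DifficultyCoefficients | None:
    if not line.startswith("# coefficients:"):
        return None
    kv = dict(tok.split("=") for tok in line.split(":", 1)[1].split())
    return DifficultyCoefficients(
        intercept=float(kv["intercept"]),
        accuracy_effect=float(kv["accuracy_effect"]),
        direction_effect=float(kv["direction_effect"]),
        discrimination=float(kv["discrimination"]),
    )


def read_bank(
    path: str | Path, coefficients: DifficultyCoefficients | None = None
) -> ItemBank:
    """Load and validate an item-bank CSV.

    Validates column layout, feature ranges, accuracy/offset consistency,
    duplicate ids, and that each stored difficulty agrees with the
    coefficients (from the file header unless overridden) to 1e-6.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        file_coeffs = _parse_bank_header(first)
        if file_coeffs is None:
            fh.seek(0)
        df = pd.read_csv(fh)
    if df.empty:
        raise FormatError("empty-input", f"{path} contains no items")
    if list(df.columns) != BANK_COLUMNS:
        raise FormatError(
            "malformed-header", f"expected columns {BANK_COLUMNS}, got {list(df.columns)}"
        )
    coeffs = coefficients or file_coeffs or PUBLISHED_COEFFICIENTS
    if df["item_id"].duplicated().any():
        dup = df["item_id"][df["item_id"].duplicated()].iloc[0]
        raise FormatError("duplicate-id", f"duplicate item_id {dup!r}")
    items = []
    for row in df.itertuples():
        predicted = float(predict_difficulty(row.accuracy, row.direction, coeffs))
        if abs(predicted - row.difficulty) > 1e-6:
            raise FormatError(
                "difficulty-mismatch",
                f"row {row.Index + 1} (item {row.item_id}): stored difficulty "
                f"{row.difficulty} disagrees with features (expected {predicted})",
            )
        try:
            items.append(
                ItemSpec(
                    item_id=str(row.item_id),
                    track_id=str(row.track_id),
                    offset=float(row.offset),
                    accuracy=float(row.accuracy),
                    direction=str(row.direction),
                    order=str(row.order),
                    difficulty=float(row.difficulty),
                )
            )
        except ValueError as exc:
            raise FormatError(
                "out-of-range", f"row {row.Index + 1} (item {row.item_id}): {exc}"
            ) from exc
    return ItemBank(items=tuple(items), coefficients=coeffs, provenance={"path": str(path)})


# -- response matrices --------------------------------------------------------

def write_matrix(matrix: ResponseMatrix, path: str | Path,
                 features_path: str | Path | None = None) -> None:
    df = pd.DataFrame(matrix.scores, index=matrix.persons, columns=matrix.items)
    df.index.name = "person_id"
    # cells are 0/1/empty
    df.map(lambda v: "" if np.isnan(v) else str(int(v))).to_csv(Path(path))
    if features_path is not None and matrix.item_features is not None:
        out = matrix.item_features.copy()
        out.index.name = "item_id"
        out.to_csv(Path(features_path))


def read_matrix(path: str | Path, features_path: str | Path | None = None) -> ResponseMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("empty-input", f"{path} is empty") from exc
    if df.empty or df.shape[1] == 0:
        raise FormatError("empty-input", f"{path} contains no responses")
    if df.index.duplicated().any():
        raise FormatError("duplicate-id", "duplicate person_id in matrix")
    if df.columns.duplicated().any():
        raise FormatError("duplicate-id", "duplicate item column in matrix")
    scores = np.full(df.shape, np.nan)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, val in enumerate(row):
            if val is np.nan or (isinstance(val, float) and np.isnan(val)) or val == "":
                continue
            if str(val).strip() not in ("0", "1"):
                raise FormatError(
                    "out-of-range",
                    f"row {i + 1} column {df.columns[j]!r}: cell {val!r} is not 0/1/empty",
                )
            scores[i, j] = float(val)
    features = None
    if features_path is not None:
        features = pd.read_csv(Path(features_path), index_col="item_id")
        missing = set(df.columns) - set(features.index.astype(str))
        if missing:
            raise FormatError(
                "missing-features", f"items without features: {sorted(missing)[:5]}"
            )
    return ResponseMatrix(
        persons=[str(p) for p in df.index],
        items=[str(c) for c in df.columns],
        scores=scores,
        item_features=features,
    )


# -- session logs (JSON lines) ------------------------------------------------

def write_session_log(result: SessionResult, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for item, resp, interim in zip(result.administered, result.responses, result.trajectory):
            fh.write(json.dumps({
                "event": "item",
                "item_id": item.item_id,
                "track_id": item.track_id,
                "accuracy": item.accuracy,
                "direction": item.direction,
                "order": item.order,
                "difficulty": item.difficulty,
                "offset": item.offset,
                "response": resp.correct,
                "theta_hat": interim.theta_hat,
                "se": interim.standard_error,
            }) + "\n")
        if result.final is not None:
            fh.write(json.dumps({
                "event": "final",
                "method": result.final.method,
                "theta_hat": result.final.theta_hat,
                "se": result.final.standard_error,
                "n_items": result.final.n_items,
                "converged": result.final.converged,
            }) + "\n")


def read_session_log(path: str | Path) -> SessionResult:
    result = SessionResult()
    for n, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FormatError("malformed-json", f"line {n}: {exc}") from exc
        if rec.get("event") == "item":
            result.administered.append(ItemSpec(
                item_id=rec["item_id"], track_id=rec["track_id"], offset=rec["offset"],
                accuracy=rec["accuracy"], direction=rec["direction"], order=rec["order"],
                difficulty=rec["difficulty"],
            ))
            result.responses.append(ScoredResponse(rec["item_id"], int(rec["response"])))
            result.trajectory.append(EstimateResult(
                rec["theta_hat"], rec["se"], "bayes_modal", True, len(result.responses)
            ))
        elif rec.get("event") == "final":
            result.final = EstimateResult(
                rec["theta_hat"], rec["se"], rec["method"], bool(rec["converged"]),
                int(rec["n_items"]),
            )
        else:
            raise FormatError("malformed-record", f"line {n}: unknown event {rec.get('event')!r}")
    if not result.administered:
        raise FormatError("empty-input", f"{path} holds no item events")
    return result


# -- beat annotations & tap takes (JSON) --------------------------------------

def write_annotation(annotation: BeatAnnotation, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "beat_times": list(annotation.beat_times),
        "mean_period": annotation.mean_period,
    }, indent=1))


def read_annotation(path: str | Path) -> BeatAnnotation:
    data = json.loads(Path(path).read_text())
    try:
        return BeatAnnotation(tuple(data["beat_times"]), float(data["mean_period"]))
    except (KeyError, ValueError) as exc:
        raise FormatError("malformed-annotation", str(exc)) from exc


def write_tap_takes(takes: list[TapTake], path: str | Path) -> None:
    Path(path).write_text(json.dumps([
        {
            "drummer_id": t.drummer_id,
            "take_id": t.take_id,
            "onsets": list(t.onsets),
            "latency_correction": t.latency_correction,
        }
        for t in takes
    ], indent=1))


def read_tap_takes(path: str | Path) -> list[TapTake]:
    data = json.loads(Path(path).read_text())
    try:
        return [
            TapTake(
                drummer_id=rec["drummer_id"],
                take_id=rec["take_id"],
                onsets=tuple(rec["onsets"]),
                latency_correction=float(rec.get("latency_correction", 0.0)),
            )
            for rec in data
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError("malformed-take", str(exc)) from exc


# -- audio --------------------------------------------------------------------

def write_wav(wave: Waveform, path: str | Path, pcm16: bool = False) -> None:
    from scipy.io import wavfile

    if pcm16:
        data = np.clip(wave.samples * 32767.0, -32768, 32767).astype(np.int16)
    else:
        data = wave.samples.astype(np.float32)
    wavfile.write(str(path), wave.sample_rate, data)
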