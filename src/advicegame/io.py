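"""Trial-log readers/writers, validation, configs and provenance.

The canonical on-disk format is a plain CSV with one row per trial and
columns ``trial, selection, p_black_P, p_black_R, degraded, advice_P,
advice_R, coin_urn, acc_P, acc_R`` (advice as signed integers, black
negative).  Metadata (seeds, configs) travels in ``# key = value`` header
comment lines.  Readers validate every invariant and reject malformed rows
with the offending line reported — nothing is silently coerced.

A generic dialect-mapping reader adapts externally deposited datasets whose
column names and value codes differ from the internal schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

TRIAL_LOG_COLUMNS = [
    "trial", "selection", "p_black_P", "p_black_R", "degraded",
    "advice_P", "advice_R", "coin_urn", "acc_P", "acc_R",
]

_SELECTIONS = {"participant", "rival"}
_URNS = {"black", "white"}
_DEGRADED = {"none", "participant", "rival"}


class TrialLogError(ValueError):
    """Schema or invariant violation in a trial log, with location."""


def validate_trial_log(df: pd.DataFrame) -> None:
    """Check schema and all trial-level invariants; raise on first violation.

    Extra columns (e.g. diagnostics such as ``w_P``) are tolerated and
    ignored.
    """
    if len(df) == 0:
        raise TrialLogError("empty trial log")
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogError(f"missing columns: {missing}")

    def bad(mask: pd.Series, what: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise TrialLogError(f"row {row} (trial {df['trial'].iloc[row]}): {what}")

    trials = df["trial"].to_numpy()
    if not np.array_equal(trials, np.arange(1, len(df) + 1)):
        raise TrialLogError("trial indices must be consecutive and 1-based")
    bad(~df["selection"].isin(_SELECTIONS), "invalid selection")
    bad(~df["degraded"].isin(_DEGRADED), "invalid degraded flag")
    bad(~df["coin_urn"].isin(_URNS), "invalid coin_urn")
    for col in ("p_black_P", "p_black_R"):
        p = pd.to_numeric(df[col], errors="coerce")
        bad(p.isna() | (p < 0) | (p > 1), f"{col} outside [0, 1]")
    for col in ("advice_P", "advice_R"):
        a = pd.to_numeric(df[col], errors="coerce")
        bad(a.isna() | (a == 0) | (a.abs() > 5) | (a != a.round()),
            f"{col} not a signed level in ±1..±5")
    for col in ("acc_P", "acc_R"):
        bad(~df[col].isin((1, -1)), f"{col} must be +1 or -1")
    # accuracy consistency: advice urn (sign) vs coin location
    for adv_col, acc_col in (("advice_P", "acc_P"), ("advice_R", "acc_R")):
        urn = np.where(df[adv_col].to_numpy(dtype=float) < 0, "black", "white")
        expect = np.where(urn == df["coin_urn"].to_numpy(), 1, -1)
        bad(pd.Series(df[acc_col].to_numpy() != expect),
            f"{acc_col} inconsistent with {adv_col} and coin_urn")


def write_trial_log(df: pd.DataFrame, path: str | Path,
                    metadata: dict | None = None) -> None:
    """Write a trial log as CSV with ``# key = value`` metadata headers."""
    path = Path(path)
    meta = dict(df.attrs)
    if metadata:
        meta.update(metadata)
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-log CSV; metadata headers land in
    ``df.attrs``."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line.lstrip("# ").partition("=")
                    meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        try:
            df = pd.read_csv(fh)
        except pd.errors.EmptyDataError:
            raise TrialLogError(f"{path}: empty trial log") from None
    try:
        validate_trial_log(df)
    except TrialLogError as exc:
        raise TrialLogError(f"{path}: {exc}") from None
    df.attrs.update(meta)
    return df


def read_cohort_dir(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read every ``*.csv`` trial log in a directory, keyed by file stem.
    ``ground_truth.csv`` and ``fne.csv`` are skipped."""
    directory = Path(directory)
    logs = {}
    for path in sorted(directory.glob("*.csv")):
        if path.stem in ("ground_truth", "fne", "config"):
            continue
        logs[path.stem] = read_trial_log(path)
    if not logs:
        raise FileNotFoundError(f"no trial logs found in {directory}")
    return logs


# ---------------------------------------------------------------------------
# Deposited-dataset adapter

def read_deposited_dataset(
    path: str | Path, mapping: dict | str | Path
) -> dict[str, pd.DataFrame]:
    """Adapt an externally deposited trial table to the internal schema.

    ``mapping`` (a dict or a JSON file) must provide:

    * ``"columns"`` — internal-name → deposited-column-name, covering every
      internal column plus ``"participant_id"``;
    * ``"values"`` (optional) — per internal column, a deposited-code →
      internal-code table (e.g. ``{"selection": {"1": "participant"}}``).

    Unmapped required columns raise a named error.  The adapted cohort is
    validated exactly like native logs.
    """
    if not isinstance(mapping, dict):
        mapping = json.loads(Path(mapping).read_text())
    columns = mapping.get("columns", {})
    required = TRIAL_LOG_COLUMNS + ["participant_id"]
    unmapped = [c for c in required if c not in columns]
    if unmapped:
        raise KeyError(f"dialect mapping lacks entries for columns: {unmapped}")
    raw = pd.read_csv(path)
    absent = [ext for ext in columns.values() if ext not in raw.columns]
    if absent:
        raise KeyError(f"deposited file lacks mapped columns: {absent}")
    df = raw[[columns[c] for c in required]].copy()
    df.columns = required
    for col, codes in mapping.get("values", {}).items():
        df[col] = df[col].astype(str).map(codes)
        if df[col].isna().any():
            raise TrialLogError(f"unmapped value code in column {col!r}")
    cohort = {}
    for pid, group in df.groupby("participant_id", sort=True):
        log = group.drop(columns="participant_id").reset_index(drop=True)
        log["trial"] = np.arange(1, len(log) + 1)
        validate_trial_log(log)
        cohort[str(pid)] = log
    return cohort


# ---------------------------------------------------------------------------
# Run configuration & provenance

@dataclass
class RunConfig:
    """Resolved settings of one pipeline run; serializable to flat JSON."""

    seed: int = 0
    preset: str = "scanner"
    n_participants: int = 30
    model: str = "interaction"
    models: tuple[str, ...] = ()
    n_samples: int = 10_000
    burn_in: int = 2_000
    n_chains: int = 4
    response_noise_sd: float = 0.3
    exclusion_min_levels: int = 3
    paths: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data["models"] = tuple(data.get("models", ()))
        return cls(**data)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def provenance(config: RunConfig) -> dict:
    """Provenance block embedded next to every artifact."""
    return {
        "package": "advicegame",
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
    }


def write_results_bundle(
    out_dir: str | Path,
    config: RunConfig,
    tables: dict[str, pd.DataFrame],
    report: dict | None = None,
) -> None:
    """Write result tables (CSV), an optional JSON report, the resolved
    config and its provenance into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.csv", index=False)
    if report is not None:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    config.to_json(out_dir / "config.json")
    (out_dir / "provenance.json").write_text(json.dumps(provenance(config), indent=2))
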