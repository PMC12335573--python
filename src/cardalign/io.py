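"""Reading and writing response tables; adapter for external study tables.

The canonical on-disk form of a cohort is a flat CSV with one row per
participant x round (the :data:`~cardalign.participants.RESPONSE_COLUMNS`
header).  Colors are encoded "red"/"black", binary flags 0/1, and the AI
confidence / true red fraction as exact integer ratios (a_num/a_den,
r_num/r_den).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .participants import RESPONSE_COLUMNS


class ResponseParseError(ValueError):
    pass


def load_run_config(path) -> dict:
    """Load a YAML run configuration into constructed parameter objects.

    Recognized top-level keys: ``master_seed`` (int), ``design`` (fields of
    :class:`~cardalign.design.DesignConfig`; ``var_a`` may be given as the
    string "3/65"), ``behavior`` (fields of
    :class:`~cardalign.participants.BehaviorParams`), ``realignment`` (fields
    of :class:`~cardalign.multical.RealignmentConfig`) and ``mcmc``
    (passed through as a dict).  Missing sections fall back to defaults.
    """
    from fractions import Fraction

    from .design import DesignConfig
    from .multical import RealignmentConfig
    from .participants import BehaviorParams

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    design_kw = dict(raw.get("design", {}))
    if "var_a" in design_kw:
        design_kw["var_a"] = Fraction(str(design_kw["var_a"]))
    return {
        "master_seed": int(raw.get("master_seed", 0)),
        "design": DesignConfig(**design_kw),
        "behavior": BehaviorParams(**raw.get("behavior", {})),
        "realignment": RealignmentConfig(**raw.get("realignment", {})),
        "mcmc": dict(raw.get("mcmc", {})),
    }


def _validate(df: pd.DataFrame, origin: str = "<records>") -> pd.DataFrame:
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseParseError(f"{origin}: missing columns {missing}")
    df = df[RESPONSE_COLUMNS].copy()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        if not (0 <= row.initial_confidence <= 100):
            raise ResponseParseError(
                f"{origin}:{idx}: initial_confidence {row.initial_confidence} "
                "outside [0, 100]"
            )
        if not (0 <= row.a_shown <= 100):
            raise ResponseParseError(
                f"{origin}:{idx}: a_shown {row.a_shown} outside [0, 100]"
            )
        for col in ("initial_guess", "final_guess"):
            v = getattr(row, col)
            if v not in ("red", "black"):
                raise ResponseParseError(f"{origin}:{idx}: {col} {v!r} not a color")
        for col in ("outcome_is_red", "is_attention_check"):
            if getattr(row, col) not in (0, 1):
                raise ResponseParseError(f"{origin}:{idx}: {col} must be 0/1")
    return df


def read_responses(path) -> pd.DataFrame:
    """Read and validate a response-table CSV; errors carry the line number."""
    df = pd.read_csv(path)
    return _validate(df, origin=str(path))


def write_responses(records: pd.DataFrame, path) -> Path:
    path = Path(path)
    _validate(records)[RESPONSE_COLUMNS].to_csv(path, index=False)
    return path


def adapt_released_dataset(path, mapping_config) -> pd.DataFrame:
    """Convert an external per-game response table to the internal schema.

    ``mapping_config`` is a YAML file path or a dict with:

    * ``columns`` — map from internal column names (the canonical header) to
      the source table's column names;
    * ``group_labels`` — map from source group labels to the internal labels
      toward/away/unbiased/realigned;
    * optionally ``attention_true_value`` — the source value that marks an
      attention-check row (default 1).

    The adapted frame is validated against all response-record invariants.
    """
    if not isinstance(mapping_config, dict):
        with open(mapping_config) as fh:
            mapping_config = yaml.safe_load(fh)
    columns = mapping_config["columns"]
    missing = [c for c in RESPONSE_COLUMNS if c not in columns]
    if missing:
        raise ResponseParseError(
            f"adapter mapping lacks source columns for {missing}"
        )
    src = pd.read_csv(path)
    absent = [s for s in columns.values() if s not in src.columns]
    if absent:
        raise ResponseParseError(f"{path}: source columns not found: {absent}")
    df = pd.DataFrame({internal: src[source] for internal, source in columns.items()})
    labels = mapping_config.get("group_labels", {})
    if labels:
        unknown = set(df["group"].unique()) - set(labels)
        if unknown:
            raise ResponseParseError(f"unmapped group labels: {sorted(unknown)}")
        df["group"] = df["group"].map(labels)
    att_true = mapping_config.get("attention_true_value", 1)
    df["is_attention_check"] = (df["is_attention_check"] == att_true).astype(int)
    return _validate(df, origin=str(path))
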