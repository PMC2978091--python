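"""File I/O: time-course TSV, model JSON, ensemble CSV, configs.

Canonical table format is tab-separated with a header
(``protein_id  condition  time_min  value  experiment_id``); comma-
separated files are accepted on read.  Values use the C locale decimal
point; decimal commas are rejected explicitly rather than silently
coerced.  Model files are schema-versioned JSON produced by
``ReactionNetwork.to_dict``.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd
import yaml

from .assimilation import ParticleEnsemble
from .network import ReactionNetwork
from .scoring import TimeCourseTable

_DECIMAL_COMMA_HINT = (
    "looks like a decimal comma (European locale); "
    "values must use '.' as the decimal separator"
)


class FormatError(ValueError):
    pass


def read_timecourse(path) -> TimeCourseTable:
    """Read a time-course table, reporting malformed rows by line number."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    first = 0  # provenance comments may precede the header
    while first < len(lines) and (not lines[first].strip()
                                  or lines[first].startswith("#")):
        first += 1
    if first >= len(lines):
        raise FormatError(f"{path}: empty file")
    header_line, lines = lines[first], lines[first:]
    delim = "\t" if "\t" in header_line else ","
    header = [h.strip() for h in header_line.split(delim)]
    required = ["protein_id", "condition", "time_min", "value"]
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    col = {name: i for i, name in enumerate(header)}
    rows = []
    for lineno, line in enumerate(lines[1:], start=first + 2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split(delim)
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
        raw_val = fields[col["value"]].strip()
        raw_time = fields[col["time_min"]].strip()
        try:
            value = float(raw_val) if raw_val not in ("", "NA", "NaN") else math.nan
        except ValueError:
            hint = _DECIMAL_COMMA_HINT if _has_decimal_comma(raw_val) else "not a number"
            raise FormatError(f"{path}:{lineno}: bad value {raw_val!r} ({hint})") from None
        try:
            t = float(raw_time)
        except ValueError:
            hint = _DECIMAL_COMMA_HINT if _has_decimal_comma(raw_time) else "not a number"
            raise FormatError(f"{path}:{lineno}: bad time {raw_time!r} ({hint})") from None
        rows.append({
            "protein_id": fields[col["protein_id"]].strip(),
            "condition": fields[col["condition"]].strip(),
            "time_min": t,
            "value": value,
            "experiment_id": fields[col["experiment_id"]].strip()
            if "experiment_id" in col else "NA",
        })
    if not rows:
        raise FormatError(f"{path}: no data rows")
    df = pd.DataFrame(rows)
    try:
        return TimeCourseTable.from_long(df)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from None


def _has_decimal_comma(s):
    import re

    return bool(re.fullmatch(r"-?\d+,\d+", s.strip()))


def write_timecourse(table: TimeCourseTable, path, header_comment=None):
    path = Path(path)
    long = table.to_long()
    with path.open("w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("protein_id\tcondition\ttime_min\tvalue\texperiment_id\n")
        for _, r in long.iterrows():
            fh.write(f"{r.protein_id}\t{r.condition}\t{r.time_min:g}\t"
                     f"{r.value:.10g}\t{r.experiment_id}\n")
    return path


def read_model(path) -> ReactionNetwork:
    with Path(path).open(encoding="utf-8") as fh:
        return ReactionNetwork.from_dict(json.load(fh))


def write_model(network: ReactionNetwork, path):
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(network.to_dict(), fh, indent=1, sort_keys=False)
        fh.write("\n")
    return path


def reaction_table(network: ReactionNetwork) -> pd.DataFrame:
    """Flat review table of the reaction list."""
    rows = []
    for r in network.reactions.values():
        rows.append({
            "reaction": r.id,
            "reactants": " + ".join(f"{v}*{k}" if v > 1 else k
                                    for k, v in r.reactants.items()),
            "products": " + ".join(f"{v}*{k}" if v > 1 else k
                                   for k, v in r.products.items()),
            "modifiers": ";".join(r.modifiers),
            "rate_law": r.rate_law,
            "parameters": ";".join(r.parameters),
        })
    return pd.DataFrame(rows)


def write_ensemble(ensemble: ParticleEnsemble, path, seed=None, config_hash=None):
    """One row per particle (weight + parameter columns); provenance in
    ``#``-comment header lines."""
    path = Path(path)
    meta = {
        "seed": ensemble.seed if seed is None else seed,
        "n_steps": ensemble.n_steps,
        "free_parameters": ",".join(ensemble.free_parameters),
        "best_loglik": ensemble.best_loglik,
    }
    if config_hash:
        meta["config_hash"] = config_hash
    with path.open("w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        ensemble.to_frame().to_csv(fh, index=False, float_format="%.10g",
                                   lineterminator="\n")
    return path


def read_ensemble(path) -> ParticleEnsemble:
    path = Path(path)
    meta = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
    df = pd.read_csv(path, comment="#")
    ens = ParticleEnsemble.from_frame(df)
    ens.seed = int(meta.get("seed", 0))
    ens.n_steps = int(meta.get("n_steps", 0))
    if meta.get("free_parameters"):
        ens.free_parameters = meta["free_parameters"].split(",")
    return ens


def load_config(path) -> dict:
    """YAML (or JSON, a YAML subset) mapping file."""
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping, for artifact headers."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
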