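"""FASTA and label I/O, prediction output, and run configuration.

Training data travels as plain FASTA with a small header dialect: the
record id is the first whitespace-delimited header token and an optional
second token carries comma-separated localization class codes, e.g.::

    >P12345 CYT,NUC
    MKV...

Prediction inputs may omit the label token.  Record splitting is done by
Biopython's FASTA parser; this module adds the dialect plus strict error
reporting (sequence before any header, empty records, duplicate ids).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .classifier import Prediction
from .errors import ConfigError, DuplicateId, MalformedFasta
from .sequences import PROFILES, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_predictions",
    "format_predictions",
    "RunConfig",
    "load_config",
]


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a (possibly labelled) multi-FASTA file.

    Blank lines are tolerated; wrapped sequence lines are joined.

    Raises
    ------
    MalformedFasta
        On sequence data before any header (with line number), an empty
        file, or a record with no sequence.
    DuplicateId
        If two records share an id.
    """
    with open(path) as fh:
        lines = fh.readlines()
    first_content = None
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            first_content = (lineno, line)
            break
    if first_content is None:
        raise MalformedFasta(f"{path}: file is empty")
    if not first_content[1].lstrip().startswith(">"):
        raise MalformedFasta(
            f"{path}: line {first_content[0]}: sequence data before any '>' header"
        )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            tokens = title.split()
            if not tokens:
                raise MalformedFasta(f"{path}: record with empty header")
            rid = tokens[0]
            labels = tuple(tokens[1].split(",")) if len(tokens) > 1 else ()
            if not seq:
                raise MalformedFasta(f"{path}: record {rid!r} has no sequence")
            if rid in seen:
                raise DuplicateId(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            records.append(SequenceRecord(rid, seq, labels))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records in the labelled-FASTA dialect (round-trip safe)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.labels else f"{rec.id} {','.join(rec.labels)}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_PRED_HEADER = (
    "seq_id\tcall\tloc1\tcs1\tloc2\tcs2\tloc3\tcs3\tmlcs\tn_skipped"
)


def format_predictions(predictions: Sequence[Prediction]) -> str:
    """Tab-separated prediction table, one row per query in input order.

    Columns: seq_id, call, then the top three (location, score) pairs,
    the MLCS and the number of skipped windows.  Scores are fixed to two
    decimals; with fewer than three classes the trailing location/score
    columns are left blank, not omitted.
    """
    if not predictions:
        raise ValueError("no predictions to write")
    lines = [_PRED_HEADER]
    for pred in predictions:
        cells = [pred.seq_id, pred.call]
        top3 = list(pred.ranked[:3])
        for i in range(3):
            if i < len(top3):
                code, cs = top3[i]
                cells += [code, f"{cs:.2f}"]
            else:
                cells += ["", ""]
        cells += [f"{pred.mlcs:.2f}", str(pred.n_skipped)]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def write_predictions(predictions: Sequence[Prediction], path) -> None:
    with open(path, "w") as fh:
        fh.write(format_predictions(predictions))


@dataclass(frozen=True)
class RunConfig:
    """Validated run options (INI file and/or CLI flags; flags win)."""

    species: str | None = None
    n: int | None = None  # None means the profile default
    alpha: float = 1.0
    mlcs_threshold: float = 60.0
    top_k: int = 3
    min_len: int = 10
    priors: str = "empirical"
    seed: int = 0
    input: str | None = None
    model: str | None = None
    output: str | None = None

    def __post_init__(self) -> None:
        if self.species is not None and self.species not in PROFILES:
            raise ConfigError(
                f"unknown species {self.species!r}; choose from {sorted(PROFILES)}"
            )
        if self.n is not None and self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")
        if not 0.0 <= self.mlcs_threshold <= 100.0:
            raise ConfigError("mlcs_threshold must be in [0, 100]")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.min_len < 1:
            raise ConfigError("min_len must be >= 1")
        if self.priors not in ("empirical", "uniform"):
            raise ConfigError("priors must be 'empirical' or 'uniform'")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")


_CONFIG_PARSERS = {
    "species": str,
    "n": lambda v: None if v == "default" else int(v),
    "alpha": float,
    "mlcs_threshold": float,
    "top_k": int,
    "min_len": int,
    "priors": str,
    "seed": int,
    "input": str,
    "model": str,
    "output": str,
}


def load_config(path, section: str = "ngloc") -> RunConfig:
    """Read an INI config file; unknown keys are rejected by name."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ConfigError(f"config file {path!r} not found or unreadable")
    if not parser.has_section(section):
        raise ConfigError(f"{path}: missing [{section}] section")
    kwargs = {}
    for key, raw in parser.items(section):
        if key not in _CONFIG_PARSERS:
            raise ConfigError(f"{path}: unknown configuration key {key!r}")
        try:
            kwargs[key] = _CONFIG_PARSERS[key](raw)
        except ValueError as exc:
            raise ConfigError(f"{path}: bad value for {key!r}: {raw!r}") from exc
    return RunConfig(**kwargs)


def merge_config(config: RunConfig, **overrides) -> RunConfig:
    """Apply non-None CLI overrides on top of a config."""
    updates = {k: v for k, v in overrides.items() if v is not None}
    return replace(config, **updates)
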