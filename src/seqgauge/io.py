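"""File formats: JSON model configs, MatrixMarket matrices, parameter TSVs,
FASTA sequence sets, and deterministic fixture generation.

All formats are plain text and all round-trips are lossless: integer-valued
matrices are written with integer entries, parameter values with full float
repr precision.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .embeddings import (
    FLAVORS,
    ONE_HOT,
    ModelSpec,
    ParameterVector,
    feature_labels,
    model_preset,
    preset_position_sets,
)
from .errors import ValidationError
from .sequence_space import Alphabet, PSCPElement, random_pscp, validate_sequence

logger = logging.getLogger("seqgauge")


# ---------------------------------------------------------------------------
# Model configuration (JSON)
# ---------------------------------------------------------------------------

def model_spec_from_dict(cfg: dict) -> ModelSpec:
    """Build a validated :class:`ModelSpec` from a configuration mapping."""
    for key in ("alphabet", "L"):
        if key not in cfg:
            raise ValidationError(f"model config is missing required field {key!r}")
    alphabet = Alphabet(cfg["alphabet"])
    L = cfg["L"]
    flavor = cfg.get("flavor", ONE_HOT)
    if flavor not in FLAVORS:
        raise ValidationError(f"field 'flavor' must be one of {FLAVORS}, got {flavor!r}")
    has_preset = "preset" in cfg
    has_sets = "position_sets" in cfg
    if has_preset == has_sets:
        raise ValidationError(
            "model config must have exactly one of 'preset' or 'position_sets'"
        )
    if has_preset:
        sets = preset_position_sets(cfg["preset"], L, cfg.get("K"))
    else:
        sets = cfg["position_sets"]
    return ModelSpec(alphabet, L, flavor, sets)


def read_model_config(path: str | Path) -> ModelSpec:
    """Read and validate a JSON model configuration file."""
    path = Path(path)
    try:
        cfg = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: model config must be a JSON object")
    spec = model_spec_from_dict(cfg)
    logger.info("loaded model config %s: M=%d, J=%d", path, spec.n_features, spec.J)
    return spec


def write_model_config(spec: ModelSpec, path: str | Path) -> None:
    cfg = {
        "alphabet": str(spec.alphabet),
        "L": spec.L,
        "flavor": spec.flavor,
        "position_sets": [list(A) for A in spec.position_sets],
    }
    Path(path).write_text(json.dumps(cfg, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Sparse matrices (MatrixMarket coordinate format)
# ---------------------------------------------------------------------------

def write_sparse_matrix(matrix, path: str | Path) -> None:
    """Write a matrix in MatrixMarket coordinate format.

    Integer-valued matrices are written with an integer field so round-trips
    are exact; degenerate 0 x N matrices are supported.
    """
    matrix = sp.coo_matrix(matrix)
    data = matrix.data
    is_int = data.size == 0 or (
        np.issubdtype(data.dtype, np.integer) or np.all(data == np.rint(data))
    )
    if is_int:
        matrix = matrix.astype(np.int64)
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, matrix, field="integer" if is_int else "real")
    Path(path).write_bytes(buf.getvalue())


def read_sparse_matrix(path: str | Path) -> sp.csr_matrix:
    """Read a MatrixMarket file back as CSR."""
    try:
        return sp.csr_matrix(scipy.io.mmread(str(path)))
    except Exception as exc:
        raise ValidationError(f"{path}: not a readable MatrixMarket file ({exc})") from exc


# ---------------------------------------------------------------------------
# Parameters (TSV)
# ---------------------------------------------------------------------------

def write_parameters(theta: ParameterVector, path: str | Path) -> None:
    lines = ["feature_label\tvalue"]
    lines += [f"{lbl}\t{float(v)!r}" for lbl, v in zip(theta.labels, theta.values)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_parameters(path: str | Path, spec: ModelSpec | None = None) -> ParameterVector:
    """Read a 2-column (feature_label, value) TSV.

    When ``spec`` is given, labels must match the model's feature labels
    exactly (any order); the returned vector follows the model's order.
    """
    path = Path(path)
    mapping: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated columns")
        label, value = parts
        if lineno == 1 and label == "feature_label":
            continue
        try:
            mapping[label] = float(value)
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: non-numeric value {value!r}") from None
    if spec is None:
        return ParameterVector(tuple(mapping), np.array(list(mapping.values())))
    labels = feature_labels(spec)
    missing = set(labels) - set(mapping)
    extra = set(mapping) - set(labels)
    if missing or extra:
        raise ValidationError(
            f"{path}: labels do not match model features "
            f"(missing {sorted(missing)[:3]}..., extra {sorted(extra)[:3]}...)"
            if len(missing) + len(extra) > 6
            else f"{path}: labels do not match model features "
            f"(missing {sorted(missing)}, extra {sorted(extra)})"
        )
    return ParameterVector(labels, [mapping[lbl] for lbl in labels])


# ---------------------------------------------------------------------------
# Sequences (FASTA)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(recs, str(path), "fasta")


def evaluate_fasta(
    spec: ModelSpec, theta: ParameterVector, records: list[tuple[str, str]]
) -> list[tuple[str, float]]:
    """Predictions ``f(s; theta)`` for a list of named sequences.

    Records with characters outside the alphabet or of the wrong length are
    rejected with the offending record id in the error message.
    """
    from .embeddings import evaluate_model

    out = []
    for name, s in records:
        try:
            validate_sequence(s, spec.alphabet, spec.L)
        except ValidationError as exc:
            logger.error("record %s rejected: %s", name, exc)
            raise ValidationError(f"record {name!r}: {exc}") from exc
        out.append((name, evaluate_model(spec, theta, s)))
    return out


def write_predictions(predictions: list[tuple[str, float]], path: str | Path) -> None:
    lines = ["id\tprediction"]
    lines += [f"{name}\t{float(v)!r}" for name, v in predictions]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("spec", "theta", "fasta", "pscp")


def make_fixture(kind: str, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Deterministically generate test inputs of the requested ``kind``.

    Always writes a random model config (``model.json``); depending on
    ``kind``, additionally writes a matching random parameter TSV
    (``theta.tsv``), a random FASTA sequence set (``sequences.fasta``) or a
    random position-specific character permutation (``pscp.json``).
    """
    if kind not in FIXTURE_KINDS:
        raise ValidationError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    alpha = int(rng.integers(2, 5))
    L = int(rng.integers(2, 5))
    alphabet = Alphabet("ABCD"[:alpha])
    n_sets = int(rng.integers(1, 5))
    sets = [()]
    for _ in range(n_sets):
        size = int(rng.integers(1, L + 1))
        sets.append(tuple(sorted(rng.choice(L, size=size, replace=False) + 1)))
    spec = ModelSpec(alphabet, L, ONE_HOT, sets)
    paths = {"spec": outdir / "model.json"}
    write_model_config(spec, paths["spec"])

    if kind == "theta":
        theta = ParameterVector(
            feature_labels(spec), rng.standard_normal(spec.n_features)
        )
        paths["theta"] = outdir / "theta.tsv"
        write_parameters(theta, paths["theta"])
    elif kind == "fasta":
        n_seqs = int(rng.integers(3, 11))
        records = [
            (f"seq{i + 1}", "".join(rng.choice(list(alphabet.chars), size=L)))
            for i in range(n_seqs)
        ]
        paths["fasta"] = outdir / "sequences.fasta"
        write_fasta(records, paths["fasta"])
    elif kind == "pscp":
        h = random_pscp(alphabet, L, rng)
        paths["pscp"] = outdir / "pscp.json"
        paths["pscp"].write_text(json.dumps({"perms": [dict(p) for p in h.perms]}, indent=1) + "\n")
    return paths


def read_pscp(path: str | Path) -> PSCPElement:
    data = json.loads(Path(path).read_text())
    return PSCPElement(data["perms"])
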