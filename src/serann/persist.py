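"""Persistence: generation logs, genotype exports, checkpoints.

Generation logs are line-delimited JSON, one object per individual per
generation, with an explicit schema version.  Genotype matrices export as
delimited text (rows = individuals, columns = sites) and as FASTA-style
records over the {0, 1} alphabet for interop with sequence tools.
Checkpoints carry a SHA-256 checksum; a tampered file refuses to load.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from .evolution import GenerationRecord, RunResult

__all__ = [
    "SCHEMA_VERSION", "IntegrityError",
    "write_generation_log", "read_generation_log",
    "export_genotypes_tsv", "export_genotypes_fasta",
    "save_checkpoint", "load_checkpoint",
]

SCHEMA_VERSION = 1


class IntegrityError(RuntimeError):
    """Checksum or schema-version mismatch."""


def write_generation_log(records: list[GenerationRecord], path) -> None:
    """One JSON object per individual per generation."""
    with open(path, "w") as fh:
        for rec in records:
            for i in range(len(rec.genotypes)):
                row = {
                    "schema": SCHEMA_VERSION,
                    "t": rec.t, "i": i,
                    "genotype": rec.genotypes[i],
                    "spec": rec.spec_texts[i],
                    "F": rec.F[i], "f": rec.f[i],
                    "N_i": rec.offspring_counts[i],
                    "Ntilde_i": rec.surviving_counts[i],
                    "drawn": rec.drawn_total[i],
                    "survived": rec.survived_total[i],
                    "parent": rec.parent_index[i],
                    "alpha": rec.alpha[i],
                    "pool_survival": rec.pool_survival[i],
                }
                fh.write(json.dumps(row) + "\n")


def read_generation_log(path) -> list[GenerationRecord]:
    by_t: dict[int, list[dict]] = {}
    with open(path) as fh:
        for line in fh:
            row = json.loads(line)
            if row.get("schema") != SCHEMA_VERSION:
                raise IntegrityError(
                    f"log schema {row.get('schema')} != {SCHEMA_VERSION}")
            by_t.setdefault(row["t"], []).append(row)
    records = []
    for t in sorted(by_t):
        rows = sorted(by_t[t], key=lambda r: r["i"])
        records.append(GenerationRecord(
            t=t,
            genotypes=[r["genotype"] for r in rows],
            spec_texts=[r["spec"] for r in rows],
            F=[r["F"] for r in rows],
            f=[r["f"] for r in rows],
            offspring_counts=[r["N_i"] for r in rows],
            surviving_counts=[r["Ntilde_i"] for r in rows],
            drawn_total=[r["drawn"] for r in rows],
            survived_total=[r["survived"] for r in rows],
            parent_index=[r["parent"] for r in rows],
            alpha=[r["alpha"] for r in rows],
            pool_survival=[r["pool_survival"] for r in rows],
        ))
    return records


def export_genotypes_tsv(genotypes, path) -> None:
    """Rows = individuals, columns = sites, tab-delimited 0/1."""
    mat = np.atleast_2d(np.asarray(
        [[int(c) for c in g] if isinstance(g, str) else g for g in genotypes],
        dtype=np.uint8))
    with open(path, "w") as fh:
        for row in mat:
            fh.write("\t".join(str(int(b)) for b in row) + "\n")


def export_genotypes_fasta(records: list[GenerationRecord], path) -> None:
    """FASTA-style records; header is >gen<t>_ind<i>, sequence over {0,1}."""
    with open(path, "w") as fh:
        for rec in records:
            for i, g in enumerate(rec.genotypes):
                fh.write(f">gen{rec.t}_ind{i}\n{g}\n")


def _payload_digest(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()


def save_checkpoint(result_or_state, path, seed: int | None = None,
                    next_t: int | None = None) -> None:
    """Persist a run (records + final genotypes) for later resume.

    Stream state is derivable: every random stream in the engine is seeded
    from (seed, generation, purpose), so (seed, next_t, genotypes) fully
    determines the continuation.
    """
    if isinstance(result_or_state, RunResult):
        res = result_or_state
        seed = res.seed if seed is None else seed
        next_t = (res.records[-1].t + 1) if next_t is None else next_t
        records = [r.to_dict() for r in res.records]
        genotypes = ["".join(str(int(b)) for b in row)
                     for row in res.final_genotypes]
    else:
        raise TypeError("expected a RunResult")
    body = json.dumps({
        "schema": SCHEMA_VERSION, "seed": seed, "next_t": next_t,
        "records": records, "genotypes": genotypes,
    }, sort_keys=True)
    with open(path, "w") as fh:
        json.dump({"checksum": _payload_digest(body), "body": body}, fh)


def load_checkpoint(path) -> dict:
    """Load a checkpoint; raises :class:`IntegrityError` on tampering."""
    with open(path) as fh:
        wrapper = json.load(fh)
    body = wrapper["body"]
    if _payload_digest(body) != wrapper["checksum"]:
        raise IntegrityError("checkpoint checksum mismatch")
    data = json.loads(body)
    if data["schema"] != SCHEMA_VERSION:
        raise IntegrityError(f"schema {data['schema']} != {SCHEMA_VERSION}")
    data["records"] = [GenerationRecord.from_dict(r) for r in data["records"]]
    data["genotypes"] = np.array(
        [[int(c) for c in g] for g in data["genotypes"]], dtype=np.uint8)
    return data
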