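"""Batch-level parallelism: many alignments over independent executors.

Alignments ``z = 1..H`` are distributed over ``P`` executors by the
congruence ``w = (z mod P) + 1``; executors share no mutable state and need
no communication.  Reproducibility rests on a simple seed-derivation
contract:

    derive_seed(r, p, k) = r + p * 1000 + k

which yields a distinct stream per (executor, worker) pair as long as
``k < 1000`` (larger ``k`` would collide with executor ``p + 1`` and is
rejected).

The content of alignment ``z`` must not depend on which executor simulates
it, otherwise changing ``P`` would change the output.  Each alignment
therefore gets an effective base seed ``r + z * 10**6`` from which its block
streams are derived; the raw per-(process, thread) formula alone cannot
provide this P-invariance.
"""

from __future__ import annotations

import hashlib
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

__all__ = [
    "derive_seed",
    "alignment_seed",
    "assign_alignments",
    "BatchSpec",
    "BatchError",
    "run_batch",
    "ALIGNMENT_SEED_STRIDE",
]

#: Offset between the base seeds of consecutive alignments in a batch.
ALIGNMENT_SEED_STRIDE = 10**6


def derive_seed(r: int, p: int, k: int) -> int:
    """Unique stream seed for worker ``k`` of executor ``p``: ``r + p*1000 + k``."""
    for label, v in (("r", r), ("p", p), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{label} must be a non-negative integer, got {v}")
    if k >= 1000:
        raise ValueError(
            f"k = {k} >= 1000 collides with the streams of executor p + 1"
        )
    return int(r) + int(p) * 1000 + int(k)


def alignment_seed(r: int, z: int) -> int:
    """Effective base seed of alignment ``z``; independent of the executor."""
    return int(r) + int(z) * ALIGNMENT_SEED_STRIDE


def assign_alignments(H: int, P: int) -> dict[int, list[int]]:
    """Map executor ``w`` (1-based) to its sorted alignment indices.

    Alignment ``z`` goes to ``w = (z mod P) + 1``; the lists partition
    ``{1..H}`` and their sizes differ by at most one.
    """
    if H < 1 or P < 1:
        raise ValueError(f"need H >= 1 and P >= 1, got H={H}, P={P}")
    out: dict[int, list[int]] = {w: [] for w in range(1, P + 1)}
    for z in range(1, H + 1):
        out[z % P + 1].append(z)
    return out


@dataclass
class BatchSpec:
    """Configuration of a batch run.

    ``out_template`` must contain a ``{z}`` placeholder for the alignment
    index.  ``algo`` selects the per-alignment algorithm ("em" or "im");
    ``K`` is the worker count inside each executor.
    """

    H: int
    P: int
    K: int
    base_seed: int
    out_template: str
    algo: str = "em"
    fmt: str = "fasta"
    lam: float | None = None

    def __post_init__(self):
        if self.H < 1 or self.P < 1 or self.K < 1:
            raise ValueError("H, P and K must all be >= 1")
        if "{z}" not in self.out_template:
            raise ValueError("out_template must contain the '{z}' placeholder")
        if self.algo not in ("em", "im"):
            raise ValueError(f"unknown algorithm {self.algo!r}")
        if self.algo == "im" and self.K < 2:
            raise ValueError("the internal-memory algorithm needs K >= 2")
        if self.base_seed < 0:
            raise ValueError("base seed must be non-negative")


class BatchError(RuntimeError):
    """One or more alignments of a batch failed."""

    def __init__(self, missing: list[int], causes: list[str]):
        self.missing = missing
        self.causes = causes
        super().__init__(
            f"batch incomplete; missing alignment indices {missing}: {'; '.join(causes)}"
        )


def _simulate_one(payload: dict, z: int) -> str:
    from .engine import SimulationTask
    from .parallel import _deserialize_task, simulate_em, simulate_im

    spec: BatchSpec = payload["spec"]
    task = _deserialize_task(payload["task"])
    task = SimulationTask(task.tree, task.model, task.site_rates, task.L,
                          alignment_seed(spec.base_seed, z))
    out = spec.out_template.format(z=z)
    try:
        if spec.algo == "em":
            simulate_em(task, spec.K, out, fmt=spec.fmt)
        else:
            simulate_im(task, spec.K, out, lam=spec.lam, fmt=spec.fmt)
    except BaseException:
        try:
            os.unlink(out)
        except OSError:
            pass
        raise
    return out


def _executor_main(payload: dict, zs: list[int]) -> list[tuple[int, str, str | None]]:
    """Run one executor's assigned alignments; never raises."""
    results = []
    for z in zs:
        try:
            results.append((z, _simulate_one(payload, z), None))
        except BaseException as exc:  # report, keep going
            results.append((z, "", f"z={z}: {exc}"))
    return results


def run_batch(spec: BatchSpec, task_template, processes: bool = True) -> list[str]:
    """Simulate all ``H`` alignments; returns output paths ordered by ``z``.

    ``task_template`` is a :class:`~msasim.engine.SimulationTask` whose seed
    is ignored (each alignment derives its own).  With ``processes=True``
    each executor is an independent OS process; the in-process mode runs the
    executors one after the other (for tests and debugging).  The produced
    files are identical either way, and for any ``P``.
    """
    from .parallel import _serialize_task

    payload = {"spec": spec, "task": _serialize_task(task_template)}
    assignment = assign_alignments(spec.H, spec.P)
    jobs = [(w, zs) for w, zs in sorted(assignment.items()) if zs]
    if processes and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=len(jobs)) as pool:
            futures = [pool.submit(_executor_main, payload, zs) for _, zs in jobs]
            results = [r for f in futures for r in f.result()]
    else:
        results = [r for _, zs in jobs for r in _executor_main(payload, zs)]

    failures = [(z, err) for z, _, err in results if err is not None]
    if failures:
        raise BatchError([z for z, _ in failures], [e for _, e in failures])
    by_z = {z: path for z, path, _ in results}
    return [by_z[z] for z in range(1, spec.H + 1)]


def file_digest(path) -> str:
    """SHA-256 of a file; used for reproducibility checks and run logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
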