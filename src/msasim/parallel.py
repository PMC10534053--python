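"""Intra-alignment parallelism.

Two algorithms simulate one alignment with several workers, both built on the
observation that without insertions/deletions the sites of the alignment
evolve independently, so disjoint contiguous site blocks can be simulated by
independent sequential runs with independent random streams.

External memory (EM)
    Phase 1: each of ``K`` workers runs the sequential engine on its site
    block, writing a temporary per-block alignment file.  Phase 2: workers
    split the tips among themselves, read each tip's subsequences from all
    temporary files, concatenate them, and write the full sequence at its
    precomputed offset in the final file.  Temporary files are removed on
    success.  Peak extra external storage equals one extra copy of the
    sequence payload.

Internal memory (IM)
    ``K - 1`` simulating workers and one dedicated writer.  Each simulating
    worker stages finished (tip, subsequence, offset) entries in a bounded
    buffer of capacity ``ceil(N * lambda)`` and blocks while the buffer is
    full; the writer polls the buffers round-robin and writes entries to
    their precomputed absolute positions.

Every block's random stream is a function of ``(base seed, block index)``
only, so the sequential-per-block reference, EM, and IM produce
byte-identical files for the same block count — a deliberately stronger
guarantee than per-configuration reproducibility.
"""

from __future__ import annotations

import math
import os
import shutil
import threading
import time
from collections import deque
from concurrent.futures import ProcessPoolExecutor, ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .distribute import derive_seed
from .engine import (
    PHYLIP_NAME_WIDTH,
    AlignmentSink,
    FastaSink,
    PhylipSink,
    ResidencyMeter,
    SimulationTask,
    SinkError,
    simulate_alignment,
)
from .model import SiteRateModel, SubstitutionModel
from .treeio import parse_newick, to_newick

__all__ = [
    "BlockPlan",
    "OutputLayout",
    "BoundedBlockBuffer",
    "partition_sites",
    "partition_tips",
    "compute_output_layout",
    "default_lambda",
    "simulate_em",
    "simulate_im",
    "simulate_reference",
    "EmStats",
    "ImStats",
    "rewrap_alignment",
]


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockPlan:
    """Contiguous half-open site ranges covering ``[0, L)``."""

    L: int
    boundaries: tuple[tuple[int, int], ...]

    @property
    def n_blocks(self) -> int:
        return len(self.boundaries)

    def lengths(self) -> list[int]:
        return [e - s for s, e in self.boundaries]


def _partition(total: int, parts: int) -> list[tuple[int, int]]:
    # Remainder goes to the lowest-indexed parts.
    base, extra = divmod(total, parts)
    out, start = [], 0
    for i in range(parts):
        size = base + (1 if i < extra else 0)
        out.append((start, start + size))
        start += size
    return out


def partition_sites(L: int, B: int) -> BlockPlan:
    """Split ``L`` sites into ``B`` contiguous blocks, lengths differing by <= 1."""
    if B < 1 or B > L:
        raise ValueError(f"need 1 <= B <= L, got B={B}, L={L}")
    return BlockPlan(L, tuple(_partition(L, B)))


def partition_tips(N: int, K: int) -> list[tuple[int, int]]:
    """Split tip indices ``0..N-1`` into ``K`` contiguous ranges."""
    if K < 1 or K > N:
        raise ValueError(f"need 1 <= K <= N, got K={K}, N={N}")
    return _partition(N, K)


def default_lambda(K: int, N: int) -> float:
    """Default buffer fraction: capacity ``ceil(N * lambda)`` = ``min(2(K-1), N)``.

    More simulating workers finish (shorter) subsequences faster, so the
    writer needs more staging room per buffer; two entries per simulating
    worker balances producer stalls against memory.
    """
    if K < 2 or N < 1:
        raise ValueError(f"need K >= 2 and N >= 1, got K={K}, N={N}")
    return min(2.0 * (K - 1) / N, 1.0)


# ---------------------------------------------------------------------------
# Output layout: absolute byte offsets of every (tip, block) record
# ---------------------------------------------------------------------------


class OutputLayout:
    """Byte geometry of a single-line FASTA or sequential PHYLIP file.

    Writing every (tip, block) subsequence at ``offset(tip, block)`` — plus
    the fixed skeleton (headers, name fields, record terminators) — yields a
    file byte-identical to the sequential append-order writer's output.
    """

    def __init__(self, tip_names: list[str], block_plan: BlockPlan, fmt: str = "fasta"):
        if len(set(tip_names)) != len(tip_names):
            raise ValueError("tip names must be unique")
        self.format = fmt
        self.tip_names = list(tip_names)
        self.block_plan = block_plan
        L, N = block_plan.L, len(tip_names)
        if fmt == "fasta":
            self.header = b""
            self._seq_starts = []
            pos = 0
            for name in self.tip_names:
                pos += 1 + len(name.encode("ascii")) + 1  # ">name\n"
                self._seq_starts.append(pos)
                pos += L + 1  # sequence + "\n"
            self.total_size = pos
        elif fmt == "phylip":
            self.header = f"{N} {L}\n".encode("ascii")
            row = PHYLIP_NAME_WIDTH + L + 1
            for name in self.tip_names:
                if len(name.encode("ascii")) > PHYLIP_NAME_WIDTH:
                    raise ValueError(
                        f"tip name {name!r} exceeds the PHYLIP name field"
                    )
            self._seq_starts = [
                len(self.header) + j * row + PHYLIP_NAME_WIDTH for j in range(N)
            ]
            self.total_size = len(self.header) + N * row
        else:
            raise ValueError(
                f"format {fmt!r} does not support direct-position writing"
            )

    def sequence_start(self, tip_index: int) -> int:
        return self._seq_starts[tip_index]

    def offset(self, tip_index: int, block_index: int) -> int:
        return self._seq_starts[tip_index] + self.block_plan.boundaries[block_index][0]

    def write_skeleton(self, fh) -> None:
        """Preallocate the file and write everything except sequence payload."""
        fh.truncate(self.total_size)
        fh.seek(0)
        fh.write(self.header)
        L = self.block_plan.L
        for j, name in enumerate(self.tip_names):
            start = self._seq_starts[j]
            if self.format == "fasta":
                fh.seek(start - len(name.encode("ascii")) - 2)
                fh.write(b">" + name.encode("ascii") + b"\n")
            else:
                fh.seek(start - PHYLIP_NAME_WIDTH)
                fh.write(name.encode("ascii").ljust(PHYLIP_NAME_WIDTH))
            fh.seek(start + L)
            fh.write(b"\n")


def compute_output_layout(tip_names, block_plan: BlockPlan, fmt: str = "fasta") -> OutputLayout:
    return OutputLayout(tip_names, block_plan, fmt)


class _OffsetSink(AlignmentSink):
    """Engine sink that forwards each tip record to a (offset, bytes) consumer."""

    def __init__(self, layout: OutputLayout, block_index: int, consume):
        self._layout = layout
        self._block = block_index
        self._consume = consume
        self._next_tip = 0

    def write(self, name: str, sequence: bytes) -> None:
        j = self._next_tip
        if self._layout.tip_names[j] != name:
            raise SinkError(
                f"tip order mismatch: expected {self._layout.tip_names[j]!r}, got {name!r}"
            )
        self._next_tip += 1
        self._consume(j, self._layout.offset(j, self._block), sequence)


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _block_task(task: SimulationTask, block: tuple[int, int]) -> SimulationTask:
    return SimulationTask(task.tree, task.model, task.site_rates,
                          block[1] - block[0], task.seed)


def _block_rng(seed: int, block_index: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, 0, block_index))


def simulate_reference(task: SimulationTask, B: int, out_path, fmt: str = "fasta") -> None:
    """Serial oracle: run the B per-block sequential simulations one after the
    other, writing each record at its layout offset."""
    plan = partition_sites(task.L, B)
    layout = compute_output_layout(task.tree.tip_names, plan, fmt)
    with open(out_path, "wb") as fh:
        layout.write_skeleton(fh)
        for b, block in enumerate(plan.boundaries):

            def consume(j, off, seq, fh=fh):
                fh.seek(off)
                fh.write(seq)

            sink = _OffsetSink(layout, b, consume)
            simulate_alignment(_block_task(task, block), sink,
                               rng=_block_rng(task.seed, b))


# ---------------------------------------------------------------------------
# External-memory algorithm
# ---------------------------------------------------------------------------


@dataclass
class EmStats:
    block_plan: BlockPlan
    phase1_seconds: float
    phase2_seconds: float
    residency_peaks: list[int]
    temp_bytes: int


def _serialize_task(task: SimulationTask) -> dict:
    srm = task.site_rates
    return {
        "newick": to_newick(task.tree),
        "exchangeabilities": task.model.exchangeabilities.tolist(),
        "frequencies": task.model.frequencies.tolist(),
        "p_inv": srm.p_inv,
        "gamma_shape": srm.gamma_shape,
        "n_categories": srm.n_categories,
        "L": task.L,
        "seed": task.seed,
    }


def _deserialize_task(payload: dict) -> SimulationTask:
    tree = parse_newick(payload["newick"])
    model = SubstitutionModel(payload["exchangeabilities"], payload["frequencies"])
    srm = SiteRateModel(payload["p_inv"], payload["gamma_shape"], payload["n_categories"])
    return SimulationTask(tree, model, srm, payload["L"], payload["seed"])


def _em_phase1_worker(args: tuple[dict, int, tuple[int, int], str, str]) -> int:
    """Simulate one site block into its temporary file; returns residency peak."""
    payload, block_index, block, tmp_path, fmt = args
    task = _deserialize_task(payload)
    block_len = block[1] - block[0]
    sub = SimulationTask(task.tree, task.model, task.site_rates, block_len, task.seed)
    if fmt == "fasta":
        sink = FastaSink(tmp_path)
    else:
        sink = PhylipSink(tmp_path, task.tree.n_tips, block_len)
    with sink:
        meter = simulate_alignment(sub, sink, rng=_block_rng(task.seed, block_index))
    return meter.peak


def _em_phase2_worker(tip_range: tuple[int, int], tmp_paths: list[str],
                      tmp_layouts: list[OutputLayout], layout: OutputLayout,
                      out_path: str) -> None:
    handles = [open(p, "rb") for p in tmp_paths]
    try:
        with open(out_path, "r+b") as out:
            for j in range(*tip_range):
                parts = []
                for b, fh in enumerate(handles):
                    fh.seek(tmp_layouts[b].sequence_start(j))
                    parts.append(fh.read(tmp_layouts[b].block_plan.L))
                out.seek(layout.sequence_start(j))
                out.write(b"".join(parts))
    finally:
        for fh in handles:
            fh.close()


def simulate_em(task: SimulationTask, K: int, out_path, workdir=None,
                fmt: str = "fasta", keep_temp: bool = False) -> EmStats:
    """External-memory parallel simulation with ``K`` worker processes."""
    if K < 1:
        raise ValueError(f"need K >= 1, got {K}")
    out_path = os.fspath(out_path)
    workdir = os.fspath(workdir) if workdir is not None else (os.path.dirname(out_path) or ".")
    plan = partition_sites(task.L, K)
    names = task.tree.tip_names
    layout = compute_output_layout(names, plan, fmt)

    need = 2 * layout.total_size
    free = shutil.disk_usage(workdir).free
    if free < need:
        raise OSError(f"insufficient disk space in {workdir}: need {need}, free {free}")

    tmp_paths = [
        os.path.join(workdir, f"{os.path.basename(out_path)}.block{b + 1}.tmp")
        for b in range(K)
    ]
    payload = _serialize_task(task)
    jobs = [(payload, b, plan.boundaries[b], tmp_paths[b], fmt) for b in range(K)]

    t0 = time.perf_counter()
    try:
        if K == 1:
            peaks = [_em_phase1_worker(jobs[0])]
        else:
            with ProcessPoolExecutor(max_workers=K) as pool:
                peaks = list(pool.map(_em_phase1_worker, jobs))
    except Exception as exc:
        _cleanup(tmp_paths + [out_path])
        raise RuntimeError(f"external-memory phase 1 failed: {exc}") from exc
    t1 = time.perf_counter()

    tmp_layouts = [
        compute_output_layout(names, partition_sites(ln, 1), fmt)
        for ln in plan.lengths()
    ]
    temp_bytes = sum(os.path.getsize(p) for p in tmp_paths)
    try:
        with open(out_path, "wb") as fh:
            layout.write_skeleton(fh)
        ranges = partition_tips(task.tree.n_tips, min(K, task.tree.n_tips))
        if len(ranges) == 1:
            _em_phase2_worker(ranges[0], tmp_paths, tmp_layouts, layout, out_path)
        else:
            with ThreadPoolExecutor(max_workers=len(ranges)) as pool:
                futures = [
                    pool.submit(_em_phase2_worker, r, tmp_paths, tmp_layouts,
                                layout, out_path)
                    for r in ranges
                ]
                for f in futures:
                    f.result()
    except Exception as exc:
        _cleanup(tmp_paths + [out_path])
        raise RuntimeError(f"external-memory phase 2 failed: {exc}") from exc
    t2 = time.perf_counter()
    if not keep_temp:
        _cleanup(tmp_paths)
    return EmStats(plan, t1 - t0, t2 - t1, peaks, temp_bytes)


def _cleanup(paths) -> None:
    for p in paths:
        try:
            os.unlink(p)
        except OSError:
            pass


# ---------------------------------------------------------------------------
# Internal-memory algorithm
# ---------------------------------------------------------------------------


class BoundedBlockBuffer:
    """Per-block staging area: at most ``capacity`` finished subsequences.

    Producers block in :meth:`push` while the buffer is full; the writer
    drains with :meth:`drain`.  Occupancy accounting is exact (peak tracked
    under the same lock as the queue).
    """

    def __init__(self, block_index: int, capacity: int):
        if capacity < 1:
            raise ValueError(f"buffer capacity must be >= 1, got {capacity}")
        self.block_index = block_index
        self.capacity = capacity
        self.closed = False
        self.peak = 0
        self.pushed = 0
        self._items: deque = deque()
        self._cv = threading.Condition()

    def push(self, entry) -> None:
        with self._cv:
            while len(self._items) >= self.capacity:
                self._cv.wait()
            self._items.append(entry)
            self.pushed += 1
            if len(self._items) > self.peak:
                self.peak = len(self._items)
            self._cv.notify_all()

    def drain(self) -> list:
        with self._cv:
            out = list(self._items)
            self._items.clear()
            self._cv.notify_all()
            return out

    def close(self) -> None:
        with self._cv:
            self.closed = True
            self._cv.notify_all()

    @property
    def finished(self) -> bool:
        with self._cv:
            return self.closed and not self._items


@dataclass
class ImStats:
    block_plan: BlockPlan
    lam: float
    capacity: int
    buffer_peaks: list[int]
    entries_pushed: int
    entries_written: int
    residency_peaks: list[int]


def simulate_im(task: SimulationTask, K: int, out_path, lam: float | None = None,
                fmt: str = "fasta", writer_backoff: float = 0.001,
                _producer_delay=None) -> ImStats:
    """Internal-memory parallel simulation: ``K - 1`` simulating threads plus
    one writer thread draining bounded buffers to precomputed file positions.

    ``lam`` is the buffer fraction (capacity ``ceil(N * lam)``); defaults to
    :func:`default_lambda`.  ``_producer_delay(block, tip)`` is a test hook
    called before each push, used to fuzz scheduling.
    """
    if K < 2:
        raise ValueError(f"internal-memory algorithm needs K >= 2, got {K}")
    N = task.tree.n_tips
    if lam is None:
        lam = default_lambda(K, N)
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"need 0 < lambda <= 1, got {lam}")
    out_path = os.fspath(out_path)
    B = K - 1
    plan = partition_sites(task.L, B)
    layout = compute_output_layout(task.tree.tip_names, plan, fmt)
    capacity = math.ceil(N * lam)
    buffers = [BoundedBlockBuffer(b, capacity) for b in range(B)]
    errors: list[BaseException] = []
    written = [0]

    def producer(b: int) -> ResidencyMeter:
        block = plan.boundaries[b]

        def consume(j, off, seq):
            if _producer_delay is not None:
                _producer_delay(b, j)
            buffers[b].push((off, seq))

        sink = _OffsetSink(layout, b, consume)
        try:
            return simulate_alignment(_block_task(task, block), sink,
                                      rng=_block_rng(task.seed, b))
        except BaseException as exc:
            errors.append(exc)
            raise
        finally:
            buffers[b].close()

    def writer(fh) -> None:
        i = 0
        try:
            while True:
                drained = buffers[i].drain()
                for off, seq in drained:
                    fh.seek(off)
                    fh.write(seq)
                    written[0] += 1
                done = all(buf.finished for buf in buffers)
                if done:
                    break
                if not drained and not any(len(buf._items) for buf in buffers):
                    time.sleep(writer_backoff)
                i = (i + 1) % B  # round-robin: i -> i mod (K-1) + 1 in 1-based terms
        except BaseException as exc:
            errors.append(exc)
            raise

    try:
        with open(out_path, "wb") as fh:
            layout.write_skeleton(fh)
        with open(out_path, "r+b") as fh:
            with ThreadPoolExecutor(max_workers=B) as pool:
                futures = [pool.submit(producer, b) for b in range(B)]
                writer_thread = threading.Thread(target=writer, args=(fh,))
                writer_thread.start()
                meters = [f.result() for f in futures]
                writer_thread.join()
        if errors:
            raise errors[0]
    except BaseException:
        _cleanup([out_path])
        raise
    return ImStats(plan, lam, capacity, [buf.peak for buf in buffers],
                   sum(buf.pushed for buf in buffers), written[0],
                   [m.peak for m in meters])


# ---------------------------------------------------------------------------
# Interoperability: re-wrap single-line records for line-length-limited tools
# ---------------------------------------------------------------------------


def rewrap_alignment(in_path, out_path, fmt: str = "fasta", width: int = 60) -> None:
    """Wrap the sequence lines of a single-line FASTA/PHYLIP file at ``width``."""
    if width < 1:
        raise ValueError(f"wrap width must be >= 1, got {width}")
    with open(in_path, "rb") as fh, open(out_path, "wb") as out:
        if fmt == "phylip":
            out.write(fh.readline())
        for line in fh:
            line = line.rstrip(b"\n")
            if fmt == "fasta" and line.startswith(b">"):
                out.write(line + b"\n")
                continue
            if fmt == "phylip":
                out.write(line[:PHYLIP_NAME_WIDTH] + b"\n")
                line = line[PHYLIP_NAME_WIDTH:]
            for i in range(0, len(line), width):
                out.write(line[i:i + width] + b"\n")
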