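"""Sequential alignment simulation along a rooted tree.

One full alignment is generated by drawing a root sequence from the stationary
frequencies, then walking the tree in preorder and sampling each node's
sequence from its parent's through the transition probabilities
``P(branch_length * site_rate)``.  Tip sequences are written to a sink in
preorder-encounter order.

Memory contract: a node's sequence is freed as soon as its last child's
sequence has been generated, so at most ``depth + 1`` full-length sequences
are ever alive at once.  :class:`ResidencyMeter` instruments this bound.

Random-draw order per alignment (pinned for reproducibility):

1. one uniform per site for the +I+Gamma category assignment,
2. one uniform per site for the root states,
3. one uniform per site per non-root node, in preorder.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .model import ModelError, SiteRateModel, SubstitutionModel
from .treeio import PhyloTree

__all__ = [
    "SimulationTask",
    "ResidencyMeter",
    "RootState",
    "sample_root_sequence",
    "evolve_sequence",
    "simulate_alignment",
    "AlignmentSink",
    "FastaSink",
    "PhylipSink",
    "open_sink",
    "SinkError",
    "PHYLIP_NAME_WIDTH",
]

#: Fixed-width name field of the sequential PHYLIP layout.
PHYLIP_NAME_WIDTH = 10


@dataclass
class SimulationTask:
    """Everything needed to simulate one alignment.

    ``seed`` is the base seed of the alignment; parallel algorithms derive
    per-block streams from it, the sequential path feeds it straight into
    ``numpy.random.default_rng``.
    """

    tree: PhyloTree
    model: SubstitutionModel
    site_rates: SiteRateModel
    L: int
    seed: int

    def __post_init__(self):
        if self.L < 1:
            raise ModelError(f"sequence length must be >= 1, got {self.L}")


@dataclass
class ResidencyMeter:
    """Counts full-length sequences concurrently alive; tracks the peak."""

    current: int = 0
    peak: int = 0

    def acquire(self) -> None:
        self.current += 1
        if self.current > self.peak:
            self.peak = self.current

    def release(self) -> None:
        self.current -= 1


class RootState(NamedTuple):
    """Root sequence plus the per-site rate assignment shared by all branches."""

    states: np.ndarray          # uint8 codes, length L
    site_rates: np.ndarray      # float rates, length L
    category_index: np.ndarray  # mixture-category index per site, length L


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _draw_states(cum3: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw; ``cum3`` holds the first three cumulative columns."""
    return (u[:, None] >= cum3).sum(axis=1).astype(np.uint8)


def sample_root_sequence(model: SubstitutionModel, site_rates: SiteRateModel,
                         L: int, rng) -> RootState:
    """Draw the root sequence i.i.d. from pi and assign per-site rates.

    The rate assignment happens once here and is reused on every branch of
    the alignment (site-homogeneous +Gamma); this is what makes disjoint
    site blocks fully independent.
    """
    rng = _as_generator(rng)
    cat_idx = site_rates.draw_categories(L, rng)
    cum3 = np.cumsum(model.frequencies)[:3][None, :]
    states = _draw_states(np.broadcast_to(cum3, (L, 3)), rng.random(L))
    return RootState(states, site_rates.mixture_rates[cat_idx], cat_idx)


def _evolve_by_category(parent: np.ndarray, branch_length: float,
                        category_index: np.ndarray, category_rates: np.ndarray,
                        model: SubstitutionModel, rng: np.random.Generator) -> np.ndarray:
    if branch_length < 0:
        raise ModelError(f"negative branch length {branch_length}")
    # One 4x4 transition matrix per rate category instead of one per site.
    cums = np.stack([model.cumulative_rows(branch_length * r) for r in category_rates])
    gathered = cums[category_index, parent]
    return _draw_states(gathered, rng.random(len(parent)))


def evolve_sequence(parent_states: np.ndarray, branch_length: float,
                    per_site_rates: np.ndarray, model: SubstitutionModel,
                    rng) -> np.ndarray:
    """Sample a child sequence site-by-site from ``P(branch_length * rate)``.

    Rate-0 (invariant) sites are copied verbatim since P(0) is the exact
    identity.
    """
    parent_states = np.asarray(parent_states, dtype=np.uint8)
    per_site_rates = np.asarray(per_site_rates, dtype=float)
    if parent_states.shape != per_site_rates.shape:
        raise ModelError("parent_states and per_site_rates lengths differ")
    rates, idx = np.unique(per_site_rates, return_inverse=True)
    return _evolve_by_category(parent_states, branch_length, idx, rates,
                               model, _as_generator(rng))


def simulate_alignment(task: SimulationTask, sink, rng=None) -> ResidencyMeter:
    """Run the sequential simulator, writing tip sequences to ``sink``.

    Returns the :class:`ResidencyMeter`; its ``peak`` never exceeds
    ``tree.depth + 1``.
    """
    rng = _as_generator(task.seed if rng is None else rng)
    tree, model = task.tree, task.model
    root_state = sample_root_sequence(model, task.site_rates, task.L, rng)
    cat_idx, cat_rates = root_state.category_index, task.site_rates.mixture_rates

    meter = ResidencyMeter()
    order = tree.preorder()
    live: dict[int, np.ndarray] = {tree.root.id: root_state.states}
    pending = {n.id: len(n.children) for n in order if n.children}
    meter.acquire()
    if not tree.root.children:  # single-node degenerate tree
        _emit(sink, tree.root.name, model, root_state.states)
        meter.release()
        return meter
    for node in order[1:]:
        child = _evolve_by_category(live[node.parent.id], node.length,
                                    cat_idx, cat_rates, model, rng)
        meter.acquire()
        if node.is_tip:
            _emit(sink, node.name, model, child)
            meter.release()
        else:
            live[node.id] = child
        parent = node.parent
        pending[parent.id] -= 1
        if pending[parent.id] == 0:
            del live[parent.id]
            meter.release()
    return meter


def _emit(sink, name: str, model: SubstitutionModel, states: np.ndarray) -> None:
    try:
        sink.write(name, model.decode(states))
    except OSError as exc:
        raise SinkError(f"writing sequence {name!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Alignment sinks.  Single-line records only: the parallel algorithms compute
# absolute byte offsets, which must be affine in the site index.
# ---------------------------------------------------------------------------


class SinkError(OSError):
    """Failure while writing alignment records."""


class AlignmentSink:
    """Append-order record writer; context manager."""

    def write(self, name: str, sequence: bytes) -> None:  # pragma: no cover
        raise NotImplementedError

    def close(self) -> None:
        pass

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False


class FastaSink(AlignmentSink):
    """``>name`` header line, sequence on a single line."""

    def __init__(self, path):
        self.path = os.fspath(path)
        self._fh = open(self.path, "wb")

    def write(self, name: str, sequence: bytes) -> None:
        self._fh.write(b">" + name.encode("ascii") + b"\n" + sequence + b"\n")

    def close(self) -> None:
        self._fh.close()


class PhylipSink(AlignmentSink):
    """Relaxed sequential PHYLIP: ``N L`` header, 10-char name field, one line per record."""

    def __init__(self, path, n_tips: int, L: int):
        self.path = os.fspath(path)
        self._fh = open(self.path, "wb")
        self._fh.write(f"{n_tips} {L}\n".encode("ascii"))

    def write(self, name: str, sequence: bytes) -> None:
        encoded = name.encode("ascii")
        if len(encoded) > PHYLIP_NAME_WIDTH:
            raise SinkError(
                f"tip name {name!r} exceeds the {PHYLIP_NAME_WIDTH}-character PHYLIP field"
            )
        self._fh.write(encoded.ljust(PHYLIP_NAME_WIDTH) + sequence + b"\n")

    def close(self) -> None:
        self._fh.close()


def open_sink(path, fmt: str, n_tips: int, L: int) -> AlignmentSink:
    if fmt == "fasta":
        return FastaSink(path)
    if fmt == "phylip":
        return PhylipSink(path, n_tips, L)
    raise ValueError(f"unsupported alignment format {fmt!r}")
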