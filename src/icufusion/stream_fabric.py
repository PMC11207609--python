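"""In-memory topic/partition broker, throughput accounting, delay simulator.

Each medical-device category maps to one topic (``Topic_PM`` for patient
monitors, ``Topic_VEN`` for ventilators, ...), sharded into partitions that
are spread across cluster nodes.  Partitions are assigned to live nodes
balanced round-robin; when a node fails only its own partitions move, and
they are re-spread onto the least-loaded survivors, so reassignment churn is
minimal and the load stays balanced by construction (successive node loads
differ by at most one partition).  Message keys route to partitions by a
stable hash, so routing is deterministic for a fixed key and live-node set.
Durability is an abstraction here (replication factor >= 2 assumed): queued
messages survive node failure, and the module guarantees conservation —
delivered count equals enqueued count under any failure schedule that leaves
at least one live node.

:func:`aggregate_stream_stats` does the unit-normalized throughput/storage
bookkeeping for a device inventory (decimal units: 1 Mbps = 1000 Kbps,
1 TB = 1000 GB).  :func:`simulate_delay` estimates the mean queueing+service
delay of an n-node cluster via per-node Lindley recursions over a shared
Poisson arrival stream with exponential service; at n=1 it is an M/M/1
system whose mean sojourn has the closed form ``1 / (mu - lambda)``.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fhir_model import ValidationError

__all__ = [
    "CATEGORY_ABBREV",
    "TopicSpec",
    "StreamCluster",
    "CategoryStreamStats",
    "StreamTotals",
    "CMUH_ICU_INVENTORY",
    "DelayEstimate",
    "ClusterDownError",
    "NodeStateError",
    "UnstableConfigurationError",
    "create_topics",
    "assign_partition",
    "aggregate_stream_stats",
    "simulate_delay",
]

#: Topic-name abbreviations per device category (``Topic_<ABBREV>``).
CATEGORY_ABBREV = {
    "patient_monitor": "PM",
    "ventilator": "VEN",
    "hemodynamics": "HM",
    "infusion_pump": "IP",
    "hematology": "HA",
    "HIS": "HIS",
    "AI": "AI",
}


class ClusterDownError(RuntimeError):
    """No live nodes remain."""


class NodeStateError(ValueError):
    """Operation on a node in the wrong state (unknown or already failed)."""


class UnstableConfigurationError(ValueError):
    """Per-node utilization >= 1; queues grow without bound."""


def stable_hash(key: str) -> int:
    """Process-independent 64-bit hash of a string key."""
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:8], "big")


@dataclass(frozen=True)
class TopicSpec:
    name: str
    category: str
    partitions: int = 64

    def __post_init__(self) -> None:
        if self.partitions < 1:
            raise ValidationError(f"partitions must be >= 1, got {self.partitions}")


def create_topics(categories: Sequence[str], partitions: int = 64) -> list[TopicSpec]:
    """One topic per category, named ``Topic_<ABBREV>``."""
    if not categories:
        raise ValidationError("categories must be non-empty")
    if len(set(categories)) != len(categories):
        dupes = sorted({c for c in categories if list(categories).count(c) > 1})
        raise ValidationError(f"duplicate categories: {dupes}")
    topics = []
    for cat in categories:
        abbrev = CATEGORY_ABBREV.get(cat)
        if abbrev is None:
            # Unknown categories get a deterministic upper-cased abbreviation.
            abbrev = "".join(w[0] for w in cat.split("_")).upper() or cat.upper()
        topics.append(TopicSpec(name=f"Topic_{abbrev}", category=cat, partitions=partitions))
    names = [t.name for t in topics]
    if len(set(names)) != len(names):
        raise ValidationError(f"topic name collision: {names}")
    return topics


class StreamCluster:
    """An n-node broker with balanced partition placement and failover."""

    def __init__(self, n_nodes: int, topics: Iterable[TopicSpec]):
        if n_nodes < 1:
            raise ValidationError(f"n_nodes must be >= 1, got {n_nodes}")
        self.topics = {t.name: t for t in topics}
        if not self.topics:
            raise ValidationError("at least one topic required")
        self.nodes = [f"node-{i}" for i in range(n_nodes)]
        self.live: set[str] = set(self.nodes)
        self.assignment: dict[tuple[str, int], str] = {}
        self.queues: dict[tuple[str, int], list] = {
            (t.name, p): [] for t in self.topics.values() for p in range(t.partitions)
        }
        self._assign_initial()

    # -- partition placement ------------------------------------------------

    def _assign_initial(self) -> None:
        # Round-robin in deterministic partition order: balanced by construction.
        live = sorted(self.live)
        for i, key in enumerate(sorted(self.queues)):
            self.assignment[key] = live[i % len(live)]

    def node_loads(self) -> dict[str, int]:
        loads = {n: 0 for n in sorted(self.live)}
        for node in self.assignment.values():
            loads[node] += 1
        return loads

    def fail_node(self, node: str) -> None:
        """Mark a node dead and re-spread its partitions onto survivors.

        Only the failed node's partitions move (minimal churn); they go to
        the least-loaded live nodes, keeping loads balanced.  Failing the
        last live node flags the cluster as down.
        """
        if node not in self.nodes:
            raise NodeStateError(f"unknown node {node!r}")
        if node not in self.live:
            raise NodeStateError(f"node {node!r} already failed")
        self.live.discard(node)
        orphans = sorted(k for k, n in self.assignment.items() if n == node)
        for k in orphans:
            del self.assignment[k]
        if not self.live:
            return  # cluster down; queues retained, is_down reports it
        loads = self.node_loads()
        for k in orphans:
            target = min(sorted(loads), key=lambda n: (loads[n], n))
            self.assignment[k] = target
            loads[target] += 1

    @property
    def is_down(self) -> bool:
        return not self.live

    # -- message routing ----------------------------------------------------

    def partition_for(self, topic: str, key: str) -> int:
        spec = self.topics.get(topic)
        if spec is None:
            raise ValidationError(f"unknown topic {topic!r}")
        return stable_hash(key) % spec.partitions

    def node_for(self, topic: str, key: str) -> str:
        if self.is_down:
            raise ClusterDownError("no live nodes")
        return self.assignment[(topic, self.partition_for(topic, key))]

    def publish(self, topic: str, key: str, value) -> str:
        """Enqueue a message; returns the node currently owning its partition."""
        p = self.partition_for(topic, key)
        if self.is_down:
            raise ClusterDownError("no live nodes")
        self.queues[(topic, p)].append((key, value))
        return self.assignment[(topic, p)]

    def drain(self) -> list[tuple[str, str, object, str]]:
        """Deliver and clear all queued messages as (topic, key, value, node)."""
        if self.is_down:
            raise ClusterDownError("no live nodes")
        out = []
        for (topic, p), queue in sorted(self.queues.items()):
            node = self.assignment[(topic, p)]
            for key, value in queue:
                out.append((topic, key, value, node))
            queue.clear()
        return out

    def enqueued_count(self) -> int:
        return sum(len(q) for q in self.queues.values())


def assign_partition(key: str, topic: str, cluster: StreamCluster) -> str:
    """Node id owning the message key's partition; deterministic for a fixed
    key and live-node set."""
    return cluster.node_for(topic, key)


# ---------------------------------------------------------------------------
# Throughput / storage aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryStreamStats:
    category: str
    units: int
    rate: float
    rate_unit: str = "Mbps"  # "Mbps" or "Kbps"
    storage: float = 0.0
    storage_unit: str = "TB"  # "TB" or "GB"

    def __post_init__(self) -> None:
        if self.rate < 0 or self.storage < 0 or self.units < 0:
            raise ValidationError(f"{self.category}: rates and capacities must be >= 0")
        if self.rate_unit not in ("Mbps", "Kbps"):
            raise ValidationError(f"unknown rate unit {self.rate_unit!r}")
        if self.storage_unit not in ("TB", "GB"):
            raise ValidationError(f"unknown storage unit {self.storage_unit!r}")

    @property
    def rate_mbps(self) -> float:
        return self.rate / 1000.0 if self.rate_unit == "Kbps" else self.rate

    @property
    def storage_tb(self) -> float:
        return self.storage / 1000.0 if self.storage_unit == "GB" else self.storage


#: Device inventory of the reference ICU deployment: five categories with
#: their unit counts, stream rates and yearly storage footprints.
CMUH_ICU_INVENTORY: tuple[CategoryStreamStats, ...] = (
    CategoryStreamStats("patient_monitor", 470, 29.7, "Mbps", 8.7, "TB"),
    CategoryStreamStats("ventilator", 180, 26.1, "Mbps", 11.3, "TB"),
    CategoryStreamStats("hemodynamics", 20, 2.32, "Mbps", 630.0, "GB"),
    CategoryStreamStats("infusion_pump", 500, 344.0, "Kbps", 1.1, "TB"),
    CategoryStreamStats("hematology", 30, 7.2, "Mbps", 6.8, "GB"),
)


@dataclass(frozen=True)
class StreamTotals:
    mbps: float  # exact sum
    tb_per_year: float  # exact sum
    mbps_rounded: float  # 2 decimals
    tb_per_year_rounded: int  # nearest TB


def aggregate_stream_stats(inventory: Iterable[CategoryStreamStats]) -> StreamTotals:
    """Exact unit-normalized totals (decimal units: 1000 Kbps/Mbps, 1000 GB/TB)."""
    inventory = list(inventory)
    # fsum keeps the totals exact and independent of category order.
    mbps = math.fsum(c.rate_mbps for c in inventory)
    tb = math.fsum(c.storage_tb for c in inventory)
    return StreamTotals(
        mbps=mbps,
        tb_per_year=tb,
        mbps_rounded=round(mbps, 2),
        tb_per_year_rounded=round(tb),
    )


# ---------------------------------------------------------------------------
# Delay simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DelayEstimate:
    mean: float
    standard_error: float
    n_messages: int
    n_nodes: int


def simulate_delay(
    n_nodes: int,
    n_topics: int,
    arrival_rate_per_topic: float,
    service_rate: float,
    n_messages: int = 200_000,
    seed: int = 0,
    n_batches: int = 40,
) -> DelayEstimate:
    """Mean queueing+service delay of an n-node cluster, with standard error.

    Messages arrive in one Poisson stream of rate ``n_topics *
    arrival_rate_per_topic`` and are routed uniformly at random across nodes
    (the key-hash limit); each node serves FIFO with exponential service at
    ``service_rate``.  Waiting times follow the Lindley recursion per node.
    The standard error uses batch means (messages split into ``n_batches``
    time-ordered batches) to absorb queueing autocorrelation.  At
    ``n_nodes=1`` the mean sojourn converges to the M/M/1 closed form
    ``1 / (service_rate - total_arrival_rate)``.
    """
    if n_nodes < 1:
        raise ValidationError(f"n_nodes must be >= 1, got {n_nodes}")
    if n_topics < 1:
        raise ValidationError(f"n_topics must be >= 1, got {n_topics}")
    lam = n_topics * arrival_rate_per_topic
    if lam <= 0 or service_rate <= 0:
        raise ValidationError("rates must be positive")
    utilization = lam / (n_nodes * service_rate)
    if utilization >= 1:
        raise UnstableConfigurationError(
            f"utilization {utilization:.3f} >= 1 (lambda={lam}, n={n_nodes}, mu={service_rate})"
        )
    rng = np.random.default_rng(seed)
    arrivals = np.cumsum(rng.exponential(1.0 / lam, n_messages))
    nodes = rng.integers(0, n_nodes, n_messages)
    service = rng.exponential(1.0 / service_rate, n_messages)
    sojourn = np.empty(n_messages)
    for node in range(n_nodes):
        mask = nodes == node
        if not mask.any():
            continue
        a = arrivals[mask]
        s = service[mask]
        waits = np.empty(a.size)
        waits[0] = 0.0
        w = 0.0
        # Lindley: W_{k} = max(0, W_{k-1} + S_{k-1} - (A_k - A_{k-1}))
        for k in range(1, a.size):
            w = max(0.0, w + s[k - 1] - (a[k] - a[k - 1]))
            waits[k] = w
        sojourn[mask] = waits + s
    batches = np.array_split(sojourn, n_batches)
    means = np.array([b.mean() for b in batches if b.size])
    se = means.std(ddof=1) / np.sqrt(means.size)
    return DelayEstimate(
        mean=float(sojourn.mean()),
        standard_error=float(se),
        n_messages=n_messages,
        n_nodes=n_nodes,
    )
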