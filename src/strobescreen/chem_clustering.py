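"""Structure-based triage of screening hits.

Hashed topological path fingerprints, Tanimoto similarity, average-linkage
hierarchical clustering cut at a similarity threshold (default 0.45), and
medoid representative selection.  Compounds merged at distance
``<= 1 - threshold`` share a cluster; one medoid per cluster is proposed for
follow-up, mirroring the screening triage where a diverse hit list collapses
to a handful of chemotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint with its generation parameters."""

    compound_id: str
    bits: np.ndarray
    params: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def make_fingerprint(
    record: CompoundRecord | str,
    *,
    compound_id: Optional[str] = None,
    n_bits: int = 2048,
    min_path: int = 1,
    max_path: int = 7,
) -> Fingerprint:
    """Hashed topological path fingerprint (RDKit) for one compound.

    Canonicalization-invariant: any SMILES of the same molecule yields the
    same bit vector.  Unparseable SMILES raise, naming the record.
    """
    if isinstance(record, str):
        record = CompoundRecord(compound_id or record, record)
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(
            f"unparseable SMILES for compound {record.compound_id!r}: {record.smiles!r}"
        )
    fp = Chem.RDKFingerprint(mol, minPath=min_path, maxPath=max_path, fpSize=n_bits)
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    return Fingerprint(
        compound_id=record.compound_id,
        bits=bits,
        params={"family": "rdkit_path", "n_bits": n_bits,
                "min_path": min_path, "max_path": max_path},
    )


def tanimoto(a: Fingerprint | np.ndarray, b: Fingerprint | np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b|; 1.0 when both vectors are empty."""
    av = a.bits if isinstance(a, Fingerprint) else np.asarray(a, dtype=bool)
    bv = b.bits if isinstance(b, Fingerprint) else np.asarray(b, dtype=bool)
    if av.size != bv.size:
        raise ValueError(f"fingerprint length mismatch: {av.size} vs {bv.size}")
    union = int(np.logical_or(av, bv).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(av, bv).sum()) / union


def tanimoto_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Dense pairwise Tanimoto similarity matrix (popcount algebra, vectorized)."""
    if not fps:
        raise ValueError("no fingerprints supplied")
    n_bits = fps[0].n_bits
    if any(f.n_bits != n_bits for f in fps):
        raise ValueError("fingerprints differ in bit length")
    X = np.stack([f.bits for f in fps]).astype(np.int64)
    inter = X @ X.T
    pop = X.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


@dataclass
class ClusterAssignment:
    """Partition of compounds from cutting a hierarchical tree at a similarity
    threshold; labels are canonicalized by each cluster's smallest compound id."""

    labels: dict[str, int]
    linkage_matrix: np.ndarray
    threshold: float
    linkage_method: str

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid, lab in self.labels.items():
            out.setdefault(lab, []).append(cid)
        return {k: sorted(v) for k, v in out.items()}


def cluster_compounds(
    fps: Sequence[Fingerprint],
    threshold: float = 0.45,
    linkage: str = "average",
) -> ClusterAssignment:
    """Hierarchical clustering on distance 1 - Tanimoto, tree cut at
    ``1 - threshold``: compounds merged at or below that distance share a cluster.

    Labels are renumbered 1..k in order of each cluster's lexicographically
    smallest member id, so the assignment is invariant to input order.
    """
    if not fps:
        raise ValueError("no fingerprints supplied")
    ids = [f.compound_id for f in fps]
    if len(set(ids)) != len(ids):
        raise ValueError("compound ids must be unique")
    if len(fps) == 1:
        return ClusterAssignment({ids[0]: 1}, np.zeros((0, 4)), threshold, linkage)
    sim = tanimoto_matrix(fps)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    # sort by id first so scipy's internal tie-breaks cannot depend on order
    order = np.argsort(ids)
    dist = dist[np.ix_(order, order)]
    ids_sorted = [ids[i] for i in order]
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    raw = hierarchy.fcluster(Z, t=1.0 - threshold, criterion="distance")
    first_member: dict[int, str] = {}
    for cid, lab in zip(ids_sorted, raw):
        first_member.setdefault(int(lab), cid)
    relabel = {
        old: new + 1
        for new, old in enumerate(sorted(first_member, key=first_member.get))
    }
    labels = {cid: relabel[int(lab)] for cid, lab in zip(ids_sorted, raw)}
    return ClusterAssignment(labels, Z, threshold, linkage)


def pick_representatives(
    assignment: ClusterAssignment, fps: Sequence[Fingerprint]
) -> dict[int, str]:
    """Medoid per cluster: the member maximizing mean intra-cluster Tanimoto
    to the other members; ties broken by lexicographic compound id."""
    by_id = {f.compound_id: f for f in fps}
    reps: dict[int, str] = {}
    for lab, members in assignment.members().items():
        if len(members) == 1:
            reps[lab] = members[0]
            continue
        best = None
        for cid in members:  # members already sorted -> lexicographic ties
            others = [tanimoto(by_id[cid], by_id[o]) for o in members if o != cid]
            score = float(np.mean(others))
            if best is None or score > best[0]:
                best = (score, cid)
        reps[lab] = best[1]
    return reps
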