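"""Protein lasso loops: extraction, classification and threading estimates.

A covalent (disulfide) bridge between two cysteines closes a backbone
loop; the chain segments before and after the bridged residues are the
tails.  Loops are classified with the same minimal-surface piercing
method used for phantom lassos (one residue = one bead, the Calpha
trace).  The fitted phantom-polymer probability surface P(N, t; L0) then
gives each loop a model threading probability; loops observed threaded
despite a very low model probability are candidate functional lassos.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from lassokit.stats import SurfaceFitParams
from lassokit.surface import (
    LassoClassLabel,
    SurfaceParams,
    count_piercings,
    span_minimal_surface,
)

__all__ = [
    "ProteinChain",
    "BridgeLoop",
    "ThreadingEstimate",
    "LoopReport",
    "ChainNotFoundError",
    "read_chain",
    "extract_lassos",
    "classify_protein_lasso",
    "threading_probability",
    "chain_threading_probability",
    "select_candidates",
    "expected_vs_observed",
]

#: SG-SG distance threshold for geometric disulfide detection, in nm
SS_BOND_CUTOFF_NM = 0.25


class ChainNotFoundError(KeyError):
    pass


@dataclass
class ProteinChain:
    chain_id: str
    residue_numbers: np.ndarray  # author residue sequence numbers
    ca_coords: np.ndarray  # (n, 3) nm
    bridges: list  # (res_i, res_j) residue-number pairs
    warnings: list = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return self.ca_coords.shape[0]


@dataclass
class BridgeLoop:
    """One bridge-closed loop with its two terminal tails.

    ``loop_coords`` runs from the first bridged residue to the second;
    the bridge edge closing the loop is implicit (last -> first vertex).
    Tails start at their bridge anchor and run outward to the terminus.
    """

    loop_coords: np.ndarray
    n: int  # loop length in residues
    tails: list  # 0-2 polylines, each anchored at a bridged residue
    tail_lengths: tuple  # (t1, t2) in residues
    bridge: tuple  # residue numbers of the bridged pair
    chain_id: str = ""


@dataclass
class ThreadingEstimate:
    p_per_tail: tuple
    p_any: float  # P(>= 1 threading) via inclusion-exclusion over tails
    p_adjusted: float  # multi-piercing adjustment (geometric model)
    observed_piercings: int = 0


@dataclass
class LoopReport:
    loop: BridgeLoop
    label: LassoClassLabel
    estimate: ThreadingEstimate
    candidate: bool = False


def _parse_ssbond_records(path: Path) -> list[tuple[str, int, str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("SSBOND"):
                try:
                    out.append(
                        (line[15], int(line[17:21]), line[29], int(line[31:35]))
                    )
                except ValueError:
                    continue
    return out


def read_chain(
    path: str | Path,
    chain_id: str,
    extra_bridges: list | None = None,
) -> ProteinChain:
    """Read one chain's Calpha trace and disulfide bridges from a PDB file.

    Bridges come from SSBOND records (authoritative), supplemented by
    geometric detection (cysteine SG-SG distance <= 2.5 Angstrom) and by
    explicit ``extra_bridges`` residue-number pairs for non-disulfide
    covalent bridges.  Coordinates are converted to nm.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise ChainNotFoundError(f"chain {chain_id!r} not in {path.name}")
    chain = model[chain_id]
    notes: list[str] = []
    res_nums = []
    coords = []
    sg: dict[int, np.ndarray] = {}
    for res in chain:
        if res.id[0] != " ":
            continue  # skip heteroatoms/water
        if "CA" not in res:
            notes.append(f"residue {res.id[1]} has no CA; dropped")
            continue
        res_nums.append(res.id[1])
        coords.append(res["CA"].coord / 10.0)  # Angstrom -> nm
        if res.get_resname() == "CYS" and "SG" in res:
            sg[res.id[1]] = res["SG"].coord / 10.0
    if not res_nums:
        raise ChainNotFoundError(f"chain {chain_id!r} has no CA atoms")
    res_nums = np.asarray(res_nums)
    gaps = np.diff(res_nums)
    for pos in np.nonzero(gaps > 3)[0]:
        notes.append(
            f"gap of {gaps[pos] - 1} residues after residue {res_nums[pos]}"
        )
    bridges: list[tuple[int, int]] = []

    def add(i: int, j: int) -> None:
        if i == j:
            return
        pair = (min(i, j), max(i, j))
        if pair[0] in res_nums and pair[1] in res_nums and pair not in bridges:
            bridges.append(pair)

    for c1, r1, c2, r2 in _parse_ssbond_records(path):
        if c1 == chain_id and c2 == chain_id:
            add(r1, r2)
    nums = sorted(sg)
    for a_i, ri in enumerate(nums):
        for rj in nums[a_i + 1 :]:
            if np.linalg.norm(sg[ri] - sg[rj]) <= SS_BOND_CUTOFF_NM:
                add(ri, rj)
    for ri, rj in extra_bridges or []:
        add(int(ri), int(rj))
    return ProteinChain(
        chain_id=chain_id,
        residue_numbers=res_nums,
        ca_coords=np.asarray(coords, dtype=np.float64),
        bridges=sorted(bridges),
        warnings=notes,
    )


def extract_lassos(chain: ProteinChain) -> list[BridgeLoop]:
    """One BridgeLoop per bridge: the loop between the bridged residues
    plus the N- and C-terminal tails (lengths in residues outside it)."""
    out = []
    for r1, r2 in chain.bridges:
        i1 = int(np.nonzero(chain.residue_numbers == r1)[0][0])
        i2 = int(np.nonzero(chain.residue_numbers == r2)[0][0])
        loop = chain.ca_coords[i1 : i2 + 1]
        t1 = i1
        t2 = chain.n_residues - 1 - i2
        tails = []
        if t1 > 0:
            tails.append(chain.ca_coords[i1::-1].copy())  # anchor -> N terminus
        if t2 > 0:
            tails.append(chain.ca_coords[i2:].copy())  # anchor -> C terminus
        out.append(
            BridgeLoop(
                loop_coords=loop.copy(),
                n=loop.shape[0],
                tails=tails,
                tail_lengths=(t1, t2),
                bridge=(r1, r2),
                chain_id=chain.chain_id,
            )
        )
    return out


def classify_protein_lasso(
    bloop: BridgeLoop, params: SurfaceParams | None = None
) -> tuple[LassoClassLabel, list]:
    """Minimal-surface classification of one bridge loop.

    The spanning surface is stretched on the Calpha loop closed by the
    bridge edge; both tails are tested for piercings (tail anchors are
    the two bridged residues, i.e. the first and last loop vertices).
    """
    params = params or SurfaceParams()
    surface = span_minimal_surface(bloop.loop_coords, params)
    totals = []
    records = []
    t1, t2 = bloop.tail_lengths
    anchors = []
    if t1 > 0:
        anchors.append(0)
    if t2 > 0:
        anchors.append(bloop.n - 1)
    for tail, anchor in zip(bloop.tails, anchors):
        rec = count_piercings(surface, tail, anchor_index=anchor)
        records.append(rec)
        totals.append(rec.totals[0])
    n_total = int(sum(totals))
    if n_total == 0:
        label = "L0"
    elif len(totals) >= 2 and all(t > 0 for t in totals):
        label = f"LL{totals[0]},{totals[1]}"
    else:
        label = f"L{n_total}"
    return LassoClassLabel(label=label, n_piercings_total=n_total), records


def threading_probability(
    bloop: BridgeLoop,
    surface_fit: SurfaceFitParams,
    observed_piercings: int = 0,
) -> ThreadingEstimate:
    """Model probability that the loop is threaded at least once.

    Per tail i, p_i = 1 - P(N, t_i; L0) from the fitted probability
    surface, clamped to [0, 1] (zero-length tails cannot thread);
    P(>=1) = 1 - prod(1 - p_i) by inclusion-exclusion under tail
    independence.  When an observed piercing count m > 1 is supplied the
    estimate is adjusted by the geometric multi-piercing model:
    P(n >= m) = P(>=1) * (1 - P_inf)^(m-1).
    """
    if surface_fit is None:
        raise ValueError("fitted probability-surface parameters are required")
    ps = []
    for t in bloop.tail_lengths:
        if t <= 0:
            ps.append(0.0)
        else:
            p_trivial = float(surface_fit(np.float64(bloop.n), np.float64(t)))
            ps.append(float(np.clip(1.0 - p_trivial, 0.0, 1.0)))
    p_any = 1.0 - float(np.prod([1.0 - p for p in ps]))
    m = max(int(observed_piercings), 1)
    p_inf = float(np.clip(surface_fit.p_inf, 1e-9, 1 - 1e-9))
    p_adj = p_any * (1.0 - p_inf) ** (m - 1)
    return ThreadingEstimate(
        p_per_tail=tuple(ps),
        p_any=p_any,
        p_adjusted=p_adj,
        observed_piercings=observed_piercings,
    )


def chain_threading_probability(estimates: list[ThreadingEstimate]) -> float:
    """P(>= 1 threaded loop on the chain), loops treated as independent."""
    p = 1.0
    for est in estimates:
        p *= 1.0 - est.p_any
    return 1.0 - p


def select_candidates(
    reports: list[LoopReport], threshold: float = 0.2, use_adjusted: bool = True
) -> list[LoopReport]:
    """Observed non-trivial loops whose model probability is below the
    threshold: threading there must be stabilised against entropy."""
    out = []
    for rep in reports:
        p = rep.estimate.p_adjusted if use_adjusted else rep.estimate.p_any
        rep.candidate = rep.label.n_piercings_total > 0 and p < threshold
        if rep.candidate:
            out.append(rep)
    return out


def expected_vs_observed(
    chain_lengths,
    p_any,
    observed_nontrivial,
    bin_width: int = 50,
    smooth_window: int = 0,
) -> pd.DataFrame:
    """Expected vs observed non-trivial chain counts per length bin.

    Expected count in a bin is the sum of per-chain threading
    probabilities; observed is the count of chains classified
    non-trivial.  ``smooth_window`` > 1 applies a centred moving average
    to both traces. Empty bins are omitted.
    """
    df = pd.DataFrame(
        {
            "length": np.asarray(chain_lengths),
            "p": np.asarray(p_any, dtype=np.float64),
            "obs": np.asarray(observed_nontrivial, dtype=bool),
        }
    )
    df["bin"] = (df["length"] // bin_width) * bin_width
    g = df.groupby("bin").agg(
        expected=("p", "sum"), observed=("obs", "sum"), n_chains=("p", "size")
    )
    g = g.reset_index()
    if smooth_window > 1:
        g["expected_smooth"] = (
            g["expected"].rolling(smooth_window, center=True, min_periods=1).mean()
        )
        g["observed_smooth"] = (
            g["observed"].rolling(smooth_window, center=True, min_periods=1).mean()
        )
    return g
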