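"""Synthetic protein-structure builders.

Constructed stand-in structures with known lasso ground truth, used by
the test suite and the protein-stage demonstration: a planar
disulfide-closed ring with a C-terminal tail threading once through it
(class L1), written as plain-text PDB.  These are not real proteins.
"""

from __future__ import annotations

import numpy as np

__all__ = ["threaded_lasso_ca_trace", "write_synthetic_lasso_pdb"]

_PDB_ATOM = (
    "ATOM  {serial:>5} {name:<4}{alt}{res:<3} {chain}{resseq:>4}{icode}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2}\n"
)


def _atom_line(serial, name, res, chain, resseq, xyz, element):
    return _PDB_ATOM.format(
        serial=serial,
        name=name if len(name) == 4 else f" {name:<3}",
        alt=" ",
        res=res,
        chain=chain,
        resseq=resseq,
        icode=" ",
        x=xyz[0],
        y=xyz[1],
        z=xyz[2],
        occ=1.0,
        b=0.0,
        element=element,
    )


def threaded_lasso_ca_trace(
    n_total: int = 40, bridge: tuple[int, int] = (5, 30)
) -> np.ndarray:
    """Synthetic CA trace (nm) with ground-truth class L1.

    Residues bridge[0]..bridge[1] form a planar circle of the right
    perimeter; the C-terminal tail dips under the plane and rises
    through the circle's centre (one upward piercing); the N-terminal
    tail stays outside and below the ring.
    """
    r1, r2 = bridge
    n_loop = r2 - r1 + 1
    step = 0.38
    radius = step / (2 * np.sin(np.pi / n_loop))
    coords = np.zeros((n_total, 3))
    th = 2 * np.pi * np.arange(n_loop) / n_loop
    coords[r1 - 1 : r2] = np.stack(
        [radius * np.cos(th), radius * np.sin(th), np.zeros(n_loop)], axis=1
    )
    start = coords[r1 - 1]
    for i in range(r1 - 2, -1, -1):
        coords[i] = start + np.array(
            [radius + (r1 - 1 - i) * step, 0.1, -0.2 - 0.05 * (r1 - 1 - i)]
        )
    k = 0
    for i in range(r2, n_total):
        k += 1
        coords[i] = np.array([0.0, 0.0, -0.3 + step * (k - 1)])
    return coords


def write_synthetic_lasso_pdb(
    path,
    ca_coords_nm: np.ndarray,
    bridge: tuple[int, int] | None = None,
    ssbond_record: bool = True,
    sg_atoms: bool = False,
    chain: str = "A",
) -> None:
    """Write a synthetic single-chain PDB (CA atoms; optionally CYS SG
    atoms 2.0 A apart at the bridge).  Input coordinates are nm."""
    lines = []
    if bridge is not None and ssbond_record:
        r1, r2 = bridge
        lines.append(f"SSBOND   1 CYS {chain} {r1:>4}    CYS {chain} {r2:>4}\n")
    serial = 1
    sg_positions = {}
    if bridge is not None and sg_atoms:
        r1, r2 = bridge
        mid = 10.0 * 0.5 * (ca_coords_nm[r1 - 1] + ca_coords_nm[r2 - 1])
        sg_positions[r1] = mid + np.array([1.0, 0.0, 0.0])
        sg_positions[r2] = mid - np.array([1.0, 0.0, 0.0])
    for i, xyz in enumerate(np.asarray(ca_coords_nm) * 10.0, start=1):
        resname = "CYS" if bridge is not None and i in bridge else "ALA"
        lines.append(_atom_line(serial, "CA", resname, chain, i, xyz, "C"))
        serial += 1
        if i in sg_positions:
            lines.append(
                _atom_line(serial, "SG", resname, chain, i, sg_positions[i], "S")
            )
            serial += 1
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
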