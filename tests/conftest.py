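from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from seqbind.datasets import AtomRecord, LigandInstance, PolymerChain
from seqbind.features import PropertyScale, PropertySet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def pdb_line(record, serial, name, resname, chain, resseq, x, y, z, element,
             altloc=" ", occ=1.0):
    return (
        f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}"
        f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


@pytest.fixture
def tiny_pdb_text():
    """Three glycine residues along the x-axis plus one ZN ion."""
    lines = []
    serial = 1
    for i, resseq in enumerate((1, 2, 3)):
        for name, elem, dy in (("N", "N", 0.0), ("CA", "C", 1.0)):
            lines.append(
                pdb_line("ATOM", serial, name, "GLY", "A", resseq, 3.8 * i, dy, 0.0, elem)
            )
            serial += 1
    lines.append(pdb_line("HETATM", serial, "ZN", "ZN", "A", 101, 0.0, 0.0, 4.0, "ZN"))
    serial += 1
    lines.append(pdb_line("HETATM", serial, "O", "HOH", "A", 201, 20.0, 20.0, 20.0, "O"))
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def aaindex_text():
    return """H TEST000101
D First test scale (hydropathy-like)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.80   -4.50   -3.50   -3.50    2.50   -3.50   -3.50   -0.40   -3.20    4.50
    3.80   -3.90    1.90    2.80   -1.60   -0.80   -0.70   -0.90   -1.30    4.20
//
H TEST000201
D Second test scale with an NA value
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.10    0.20      NA    0.40    0.50    0.60    0.70    0.80    0.90    1.00
    1.10    1.20    1.30    1.40    1.50    1.60    1.70    1.80    1.90    2.00
//
H TEST000301
D Third test scale (volume-like)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   88.60  173.40  114.10  111.10  108.50  143.80  138.40   60.10  153.20  166.70
  166.70  168.60  162.90  189.90  112.70   89.00  116.10  227.80  193.60  140.00
//
"""


def single_atom_chain(x=0.0, y=0.0, z=0.0, element="C", resname="ALA"):
    atom = AtomRecord(element=element, residue_index=0, chain_id="A",
                      x=x, y=y, z=z, record_class="polymer", residue_name=resname)
    return PolymerChain(chain_id="A", sequence="A", residues=[[atom]])


def point_ligand(x, y, z, element="ZN", code="ZN"):
    atom = AtomRecord(element=element, residue_index=0, chain_id="A",
                      x=x, y=y, z=z, record_class="ligand", residue_name=code)
    return LigandInstance(het_code=code, chemical_class="metal", atoms=[atom])


def random_property_set(n: int, seed: int = 0) -> PropertySet:
    """Independent random scales packaged directly as a PropertySet."""
    rng = np.random.default_rng(seed)
    scales = [
        PropertyScale(f"RND{i:04d}", "random scale", tuple(rng.standard_normal(20)))
        for i in range(n)
    ]
    return PropertySet(scales=scales, threshold=0.5)
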