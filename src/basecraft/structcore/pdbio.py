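"""PDB reading/writing behind the :class:`ProteinStructure` contract.

Parsing is delegated to gemmi; this wrapper enforces the contracts gemmi is
lenient about: malformed coordinate fields are reported with their line
number, duplicate atom keys are an error, and the altloc policy
(highest-occupancy / keep-all / a specific label) is applied here.
"""

from __future__ import annotations

import gemmi
import numpy as np

from .model import AtomRecord, ProteinStructure, ResidueView

__all__ = ["parse_pdb", "write_pdb", "ALTLOC_POLICIES"]

ALTLOC_POLICIES = ("highest_occupancy", "keep_all", "label")

_COORD_SLICES = ((30, 38), (38, 46), (46, 54), (54, 60), (60, 66))


def _prevalidate(text: str):
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        for lo, hi in _COORD_SLICES:
            fld = line[lo:hi].strip()
            if fld == "" and lo >= 54:  # occupancy/bfactor may be blank
                continue
            try:
                float(fld)
            except ValueError:
                raise ValueError(
                    f"malformed coordinate field {fld!r} on line {lineno}: {line.rstrip()!r}"
                ) from None


def _apply_altloc_policy(atoms: list[AtomRecord], policy: str, label: str) -> list[AtomRecord]:
    if policy == "keep_all":
        return atoms
    if policy == "label":
        return [a for a in atoms if a.altloc in ("", label)]
    # highest_occupancy: group by atom name, keep the highest-occupancy
    # conformer; ties broken by altloc label order (A before B).
    by_name: dict[str, list[AtomRecord]] = {}
    order = []
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
        if a.name not in order:
            order.append(a.name)
    kept = []
    for n in order:
        group = sorted(by_name[n], key=lambda a: (-a.occupancy, a.altloc))
        kept.append(group[0])
    return kept


def parse_pdb(
    text: str,
    altloc_policy: str = "highest_occupancy",
    altloc_label: str = "A",
) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Multi-MODEL files become trajectory models.  ``altloc_policy`` is one of
    ``highest_occupancy`` (default; ties broken A-first), ``keep_all`` or
    ``label`` (keep blank + ``altloc_label``).
    """
    if altloc_policy not in ALTLOC_POLICIES:
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    _prevalidate(text)
    st = gemmi.read_pdb_string(text)
    models = []
    for gm in st:
        residues = []
        seen = set()
        for chain in gm:
            for res in chain:
                atoms = []
                for at in res:
                    alt = at.altloc if at.altloc not in ("", "\0") else ""
                    key = (chain.name, res.seqid.num, alt, at.name)
                    if key in seen:
                        raise ValueError(f"duplicate atom key {key}")
                    seen.add(key)
                    atoms.append(
                        AtomRecord(
                            name=at.name,
                            element=at.element.name,
                            pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=min(max(at.occ, 0.0), 1.0),
                            altloc=alt,
                            bfactor=at.b_iso,
                            is_hetero=res.het_flag == "H",
                        )
                    )
                atoms = _apply_altloc_policy(atoms, altloc_policy, altloc_label)
                residues.append(
                    ResidueView(chain=chain.name, seqnum=res.seqid.num, name=res.name, atoms=atoms)
                )
        models.append(residues)
    return ProteinStructure(models or [[]], title=st.name or "")


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize to PDB text; round-trips coordinates to the format's 3 decimals.

    Atom names longer than 4 characters and residue numbers above 9999 are
    rejected (no hybrid-36 extension).
    """
    st = gemmi.Structure()
    st.name = structure.title or "basecraft"
    for m_idx, residues in enumerate(structure.models, start=1):
        gm = gemmi.Model(m_idx)
        chains: dict[str, gemmi.Chain] = {}
        for r in residues:
            if r.chain not in chains:
                chains[r.chain] = gemmi.Chain(r.chain)
            gr = gemmi.Residue()
            gr.name = r.name
            if r.seqnum > 9999 or r.seqnum < -999:
                raise ValueError(f"residue number {r.seqnum} outside plain-PDB range")
            gr.seqid = gemmi.SeqId(r.seqnum, " ")
            gr.het_flag = "H" if any(a.is_hetero for a in r.atoms) else "A"
            for a in r.atoms:
                if len(a.name) > 4:
                    raise ValueError(f"atom name {a.name!r} longer than 4 characters")
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occupancy
                ga.altloc = a.altloc if a.altloc else "\0"
                ga.b_iso = a.bfactor
                gr.add_atom(ga)
            chains[r.chain].add_residue(gr)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    return st.make_pdb_string()
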