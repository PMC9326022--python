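"""Optional SVG depiction of matched alert fragments (highlighted atoms)."""

from __future__ import annotations

from pathlib import Path

from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from .chem import Compound
from .screening import ScreeningResult

_HIGHLIGHT = (0.9, 0.2, 0.2)  # red, per the usual alert-hit rendering


def draw_match_svg(
    compound: Compound | Chem.Mol,
    atom_indices: tuple[int, ...] | list[int],
    size: tuple[int, int] = (350, 300),
) -> str:
    """SVG of the compound with the matched atoms highlighted."""
    mol = compound.mol() if isinstance(compound, Compound) else compound
    drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol,
        highlightAtoms=list(atom_indices),
        highlightAtomColors={i: _HIGHLIGHT for i in atom_indices},
    )
    drawer.FinishDrawing()
    return drawer.GetDrawingText()


def export_result_svgs(
    compound: Compound, result: ScreeningResult, outdir: str | Path
) -> list[Path]:
    """One SVG per matched alert (first embedding), named by alert id."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for match in result.matches:
        path = outdir / f"{result.query_id}_{match.alert_id}.svg"
        path.write_text(draw_match_svg(compound, match.atom_index_lists[0]))
        written.append(path)
    return written
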