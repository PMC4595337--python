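"""Bundled worked-example inputs.

The Levivirus (bacteriophage MS2) coat protein is the classic small
protein/RNA-hairpin system used as the low-disorder, small-interface end of
the interface-size spectrum.  Its SwissProt sequence (P03612) ships with the
package; the crystal-structure coordinates of the complex do not (they are
fetched on demand, see :func:`fetch_pdb`).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .errors import InputError
from .io_formats import SequenceRecord, read_fasta

COAT_PROTEIN_PDB_ID = "1AQ3"


def coat_protein_record() -> SequenceRecord:
    """The MS2/Levivirus coat-protein sequence (SwissProt P03612)."""
    with resources.as_file(
        resources.files("discons") / "data" / "levivirus_coat_p03612.fasta"
    ) as path:
        return read_fasta(path)[0]


def fetch_pdb(pdb_id: str, dest_dir) -> Path:
    """Download a PDB entry from RCSB (thin helper; requires network access)."""
    import urllib.request

    dest = Path(dest_dir) / f"{pdb_id.lower()}.pdb"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=30) as response:
            dest.write_bytes(response.read())
    except Exception as exc:
        raise InputError(f"could not fetch {pdb_id} from RCSB: {exc}") from exc
    return dest
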