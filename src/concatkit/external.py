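"""Subprocess adapters to externally installed alignment/tree programs.

The package never bundles or re-implements an aligner or tree builder;
these helpers shell out to MAFFT and FastTree when they are installed on
PATH and raise :class:`ExternalToolError` with a clear message when they
are not.  Nothing else in the package (and none of the tests) depends on
either binary being available.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .datamodel import MarkerBlock
from .errors import ExternalToolError
from .io_formats import read_fasta, write_fasta

#: MAFFT strategy flags: fast is FFT-NS-1, thorough is G-INS-i, auto lets
#: MAFFT choose between them.
MAFFT_STRATEGIES = {
    "auto": ["--auto"],
    "fast": ["--retree", "2", "--maxiterate", "0"],
    "thorough": ["--globalpair", "--maxiterate", "1000"],
}


def _require(binary: str) -> str:
    path = shutil.which(binary)
    if path is None:
        raise ExternalToolError(
            f"external program {binary!r} not found on PATH; install it or "
            "skip the step that needs it"
        )
    return path


def align_with_mafft(
    block: MarkerBlock, strategy: str = "auto", binary: str = "mafft"
) -> MarkerBlock:
    """Align one marker with an external MAFFT and return the new block."""
    if strategy not in MAFFT_STRATEGIES:
        raise ExternalToolError(
            f"unknown alignment strategy {strategy!r}; "
            f"choose from {sorted(MAFFT_STRATEGIES)}"
        )
    exe = _require(binary)
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        infile.write_text(write_fasta(block, line_width=0), encoding="utf-8")
        result = subprocess.run(
            [exe, *MAFFT_STRATEGIES[strategy], str(infile)],
            capture_output=True,
            text=True,
        )
        if result.returncode != 0:
            raise ExternalToolError(
                f"mafft failed on marker {block.marker_name!r}: "
                f"{result.stderr.strip()[:500]}"
            )
        outfile = Path(tmp) / "out.fasta"
        outfile.write_text(result.stdout, encoding="utf-8")
        aligned = read_fasta(outfile, marker_name=block.marker_name)
    return aligned


def build_tree_fasttree(
    block_or_alignment, binary: str = "fasttree"
) -> str:
    """Approximate-ML tree (newick) from an alignment via external FastTree."""
    exe = _require(binary)
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        infile.write_text(
            write_fasta(block_or_alignment, line_width=0), encoding="utf-8"
        )
        result = subprocess.run(
            [exe, "-nt", "-quiet", str(infile)],
            capture_output=True,
            text=True,
        )
    if result.returncode != 0:
        raise ExternalToolError(
            f"fasttree failed: {result.stderr.strip()[:500]}"
        )
    return result.stdout.strip()
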