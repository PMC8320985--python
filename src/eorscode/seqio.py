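"""Reading and writing codeword lists as plain text or FASTA.

Text format: one sequence per line, blank lines and ``#`` comments ignored.
FASTA records are named ``cw_0001`` ... and wrapped at 60 columns.  Words
may be written in their quaternary digit form (T=0, C=1, G=2, A=3) with
``digits=True``; digit lines are recognised transparently on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CodeSet, Codeword, ConstraintProfile

__all__ = [
    "read_words",
    "write_words",
    "read_fasta",
    "write_fasta",
    "load_code",
    "save_code",
]

_DIGIT_CHARS = set("0123")


def _parse_token(tok: str) -> Codeword:
    if tok and set(tok) <= _DIGIT_CHARS:
        return Codeword.from_digits(int(c) for c in tok)
    return Codeword(tok)


def read_words(path: str | Path) -> list[Codeword]:
    """Read one word per line; '#' starts a comment, blank lines ignored."""
    words = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        words.append(_parse_token(line))
    return words


def write_words(
    words: Iterable[Codeword], path: str | Path, digits: bool = False
) -> None:
    lines = []
    for w in words:
        lines.append("".join(str(d) for d in w.digits) if digits else w.bases)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_fasta(path: str | Path) -> list[Codeword]:
    return [Codeword(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(words: Sequence[Codeword], path: str | Path) -> None:
    width = len(f"{max(len(words), 1)}")
    width = max(width, 4)
    records = [
        SeqRecord(Seq(w.bases), id=f"cw_{i + 1:0{width}d}", description="")
        for i, w in enumerate(words)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def load_code(
    path: str | Path, profile: ConstraintProfile, fmt: str | None = None
) -> CodeSet:
    """Load a codeword list into a CodeSet (format inferred from suffix)."""
    fmt = fmt or _infer_format(path)
    words = read_fasta(path) if fmt == "fasta" else read_words(path)
    return CodeSet(profile, words)


def save_code(
    code: CodeSet, path: str | Path, fmt: str | None = None, digits: bool = False
) -> None:
    fmt = fmt or _infer_format(path)
    if fmt == "fasta":
        write_fasta(list(code.members), path)
    else:
        write_words(code.members, path, digits=digits)


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return "fasta" if suffix in {".fa", ".fasta", ".fna"} else "text"
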