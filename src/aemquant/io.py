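"""Plain-text formats: FASTA, equivalence-class counts, design-matrix TSVs.

All formats are line-oriented text for auditability. Equivalence-class
counts come in two dialects:

* ``salmon`` — the ``eq_classes.txt`` layout: line 1 the number of
  transcripts, line 2 the number of classes, then one transcript name per
  line, then one line per class ``k idx1 ... idxk count`` with 0-based
  transcript indices into the name list.
* ``tsv`` — one line per class: comma-joined transcript ids, a tab, the count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aem import AbundanceMatrix
from .matrix import DesignMatrix, pattern_string
from .simgen import EqclassCounts, ToyTranscript
from .xbuilder import TRP

__all__ = [
    "RunConfig",
    "write_fasta",
    "read_fasta",
    "write_eqclass_file",
    "read_eqclass_file",
    "write_design_tsv",
    "read_design_tsv",
    "write_trp_tsv",
    "write_counts_tsv",
    "write_diagnostics",
]


class FormatError(ValueError):
    """Raised on malformed input files, with the offending line number."""


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run; written next to the outputs."""

    seed: int = 0
    H: float = 0.025
    sv_threshold: float = 0.02
    rel_tol: float = 0.01
    max_iter: int = 100
    literal_eq7: bool = False
    update_X: bool = True
    n_genes: int = 5
    isoforms_per_gene: int = 3
    n_samples: int = 20
    base_error_rate: float = 0.005
    read_length: int = 100
    bias_strength: float = 0.0
    paths: dict[str, str] = field(default_factory=dict)
    log_level: str = "INFO"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


# -- FASTA ----------------------------------------------------------------

def write_fasta(path: str | Path, transcripts: list[ToyTranscript]) -> None:
    """Write transcripts as 80-column FASTA with ``>id gene=geneid`` headers."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=f"gene={t.gene_id}")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ToyTranscript]:
    transcripts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        transcripts.append(ToyTranscript(rec.id, str(rec.seq).upper(), gene))
    return transcripts


# -- equivalence-class counts ---------------------------------------------

def write_eqclass_file(
    path: str | Path,
    counts: EqclassCounts,
    dialect: str = "salmon",
    transcript_order: list[str] | None = None,
) -> None:
    """Serialize eqclass counts in the ``salmon`` or ``tsv`` dialect.

    ``transcript_order`` fixes the salmon header name list (defaults to the
    sorted union of all class members).
    """
    classes = sorted(counts.counts.items(), key=lambda kv: sorted(kv[0]))
    if dialect == "tsv":
        lines = [
            f"{','.join(sorted(eqclass))}\t{count}" for eqclass, count in classes
        ]
    elif dialect == "salmon":
        if transcript_order is None:
            transcript_order = sorted(set().union(*counts.counts.keys())) if counts.counts else []
        index = {t: i for i, t in enumerate(transcript_order)}
        missing = set().union(*counts.counts.keys(), frozenset()) - set(index)
        if missing:
            raise ValueError(f"transcript_order is missing {sorted(missing)}")
        lines = [str(len(transcript_order)), str(len(classes))]
        lines.extend(transcript_order)
        for eqclass, count in classes:
            idx = sorted(index[t] for t in eqclass)
            lines.append(" ".join([str(len(idx)), *map(str, idx), str(count)]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_eqclass_file(path: str | Path, dialect: str = "salmon") -> EqclassCounts:
    """Parse an eqclass count file; malformed lines raise with their number."""
    lines = Path(path).read_text().splitlines()
    counts: dict[frozenset[str], int] = {}
    if dialect == "tsv":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                ids, count = line.split("\t")
                eqclass = frozenset(ids.split(","))
                counts[eqclass] = counts.get(eqclass, 0) + int(count)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line {line!r}") from exc
        return EqclassCounts(counts)
    if dialect != "salmon":
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        n_transcripts = int(lines[0])
        n_classes = int(lines[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}:1-2: malformed header") from exc
    names = lines[2 : 2 + n_transcripts]
    if len(names) != n_transcripts:
        raise FormatError(f"{path}: header declares {n_transcripts} transcripts, found {len(names)}")
    class_lines = [l for l in lines[2 + n_transcripts :] if l.strip()]
    if len(class_lines) != n_classes:
        raise FormatError(
            f"{path}: header declares {n_classes} classes, found {len(class_lines)}"
        )
    for offset, line in enumerate(class_lines):
        lineno = 3 + n_transcripts + offset
        fields = line.split()
        try:
            k = int(fields[0])
            idx = [int(v) for v in fields[1 : 1 + k]]
            count = int(fields[1 + k])
            if len(fields) != k + 2:
                raise ValueError("wrong field count")
            eqclass = frozenset(names[i] for i in idx)
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed class line {line!r}") from exc
        counts[eqclass] = counts.get(eqclass, 0) + count
    return EqclassCounts(counts)


# -- design matrix / profiles / outputs -----------------------------------

def write_design_tsv(path: str | Path, X: DesignMatrix) -> None:
    """First column the pattern bit string, one column per transcript."""
    df = pd.DataFrame(X.x, columns=X.transcripts)
    df.insert(0, "pattern", X.pattern_strings())
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_design_tsv(path: str | Path) -> DesignMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"pattern": str})
    patterns = [tuple(int(c) for c in p) for p in df["pattern"]]
    transcripts = [c for c in df.columns if c != "pattern"]
    dm = DesignMatrix(transcripts, patterns, df[transcripts].to_numpy(dtype=float))
    dm.validate()
    return dm


def write_trp_tsv(path: str | Path, trp: TRP) -> None:
    """Profile table: one row per eqclass, one column per member, plus a Sum row."""
    members = sorted(trp.members)
    rows = []
    for i, (eqclass, count) in enumerate(trp.rows.items(), start=1):
        rows.append(
            [f"eqclass{i}", *[count if m in eqclass else 0 for m in members]]
        )
    totals = trp.totals
    rows.append(["Sum", *[totals.get(m, 0) for m in members]])
    df = pd.DataFrame(rows, columns=["eqclass", *members])
    df.to_csv(path, sep="\t", index=False)


def write_counts_tsv(path: str | Path, abundances: AbundanceMatrix) -> None:
    """Estimated read counts (prior offset removed), transcripts x samples."""
    df = pd.DataFrame(
        abundances.counts,
        index=abundances.transcripts,
        columns=abundances.sample_names,
    )
    df.index.name = "transcript"
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_diagnostics(path: str | Path, diagnostics, extra: dict | None = None) -> None:
    payload = diagnostics.to_dict() if hasattr(diagnostics, "to_dict") else dict(diagnostics)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
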