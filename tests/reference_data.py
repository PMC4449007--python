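"""Access to public reference sequences used by the reproduction tests.

Each getter first looks for a user-supplied copy under ``data/reference/``
at the repository root, then attempts a short-timeout download from the
public archive.  When neither source is available a RuntimeError explains
what to provide; the reproduction tests then fail with that message rather
than silently skipping.
"""

from __future__ import annotations

import io
import urllib.request
from pathlib import Path

REFERENCE_DIR = Path(__file__).resolve().parent.parent / "data" / "reference"
TIMEOUT = 8.0

UNIPROT_FASTA = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"
UNIPROT_GENE_QUERY = (
    "https://rest.uniprot.org/uniprotkb/search?format=fasta&size=1&query="
    "gene_exact:{gene}+AND+organism_id:3702+AND+reviewed:true"
)
NCBI_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&id={ids}&rettype=fasta&retmode=text"
)


def _fetch(url: str) -> bytes:
    req = urllib.request.Request(url, headers={"User-Agent": "gt43scan-tests"})
    with urllib.request.urlopen(req, timeout=TIMEOUT) as resp:
        return resp.read()


def _local_or_fetch(local_name: str, url: str, what: str) -> bytes:
    local = REFERENCE_DIR / local_name
    if local.exists():
        return local.read_bytes()
    try:
        return _fetch(url)
    except Exception as exc:
        raise RuntimeError(
            f"{what} is unavailable: no local copy at {local} and the "
            f"download failed ({exc}).  Place the file at that path to run "
            "this reproduction test offline."
        ) from exc


def _parse_fasta_bytes(data: bytes) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in io.StringIO(data.decode()):
        line = line.strip()
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line:
            chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def glcat1_sequence() -> str:
    """Human GlcAT-I, UniProt O94766 (335 aa)."""
    data = _local_or_fetch(
        "O94766.fasta", UNIPROT_FASTA.format(acc="O94766"),
        "the human GlcAT-I sequence (UniProt O94766)",
    )
    (seq,) = _parse_fasta_bytes(data).values()
    return seq


def genbank_proteins(accessions: list[str]) -> dict[str, str]:
    """Protein sequences for GenBank accessions, keyed by accession."""
    data = _local_or_fetch(
        "genbank21.fasta", NCBI_EFETCH.format(ids=",".join(accessions)),
        "the 21 GenBank protein records",
    )
    parsed = _parse_fasta_bytes(data)
    out: dict[str, str] = {}
    for acc in accessions:
        for key, seq in parsed.items():
            if key.startswith(acc) or acc.startswith(key):
                out[acc] = seq
                break
    return out


def arabidopsis_protein(gene: str) -> str:
    """A reviewed Arabidopsis protein by gene symbol (e.g. IRX9)."""
    data = _local_or_fetch(
        f"{gene}.fasta", UNIPROT_GENE_QUERY.format(gene=gene),
        f"the Arabidopsis {gene} sequence",
    )
    values = list(_parse_fasta_bytes(data).values())
    if not values:
        raise RuntimeError(f"no sequence returned for gene {gene}")
    return values[0]


def transcriptome_peptides() -> dict[str, str]:
    """The 54 transcriptome-derived peptides.

    This set is distributed as a supplementary workbook of the source
    study and has no stable fetch URL, so a local copy is required: either
    the original workbook at ``data/reference/peptides54.xlsx`` or a FASTA
    extraction at ``data/reference/peptides54.fasta`` (IDs like
    ``C.brebissonii|Locus_12``).
    """
    local_fasta = REFERENCE_DIR / "peptides54.fasta"
    if local_fasta.exists():
        return _parse_fasta_bytes(local_fasta.read_bytes())
    local_xlsx = REFERENCE_DIR / "peptides54.xlsx"
    if local_xlsx.exists():
        return _peptides_from_xlsx(local_xlsx.read_bytes())
    raise RuntimeError(
        "the 54 transcriptome-derived peptides are unavailable: place the "
        f"supplementary workbook at {local_xlsx} or a FASTA extraction at "
        f"{local_fasta} to run this reproduction test."
    )


def _peptides_from_xlsx(data: bytes) -> dict[str, str]:
    from openpyxl import load_workbook

    wb = load_workbook(io.BytesIO(data), read_only=True)
    ws = wb.active
    rows = list(ws.iter_rows(values_only=True))
    header = [str(c).strip().lower() if c else "" for c in rows[0]]
    id_col = next(
        i for i, h in enumerate(header) if "id" in h or "locus" in h
    )
    seq_col = next(
        i for i, h in enumerate(header)
        if "seq" in h or "peptide" in h or "protein" in h
    )
    out: dict[str, str] = {}
    for row in rows[1:]:
        if row[id_col] and row[seq_col]:
            out[str(row[id_col]).strip()] = (
                str(row[seq_col]).replace(" ", "").replace("*", "").strip()
            )
    return out
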