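"""Retrieve and prepare the published primate AVP/AVPR1a coding sequences.

Downloads the study's GenBank accessions (KJ641423-KJ641466) plus the human
and *Microcebus* reference CDSs, extracts the annotated CDS from each record,
splits records into the short AVP gene (27 nt coding region) and the AVPR1a
receptor gene, aligns each gene in frame (protein alignment with mafft,
threaded back onto the nucleotides), and writes:

    data/real/avp_aligned.fasta
    data/real/avpr1a_aligned.fasta
    data/real/metadata.tsv        (taxon, genus, family, group, monogamy
                                   columns left for manual curation)

Requires network access to NCBI and `mafft` on PATH.  Run from the
repository root:

    python scripts/fetch_real_data.py --email you@example.org
"""

from __future__ import annotations

import argparse
import subprocess
import sys
import tempfile
from io import StringIO
from pathlib import Path

from Bio import Entrez, SeqIO

STUDY_ACCESSIONS = [f"KJ6414{n}" for n in range(23, 67)]  # KJ641423..KJ641466
REFERENCE_ACCESSIONS = [
    "NM_000706",  # human AVPR1A mRNA
    "NM_000490",  # human AVP mRNA
]


def fetch_cds(accessions: list[str]) -> dict[str, str]:
    """Accession -> CDS nucleotide string (first annotated CDS per record)."""
    handle = Entrez.efetch(
        db="nuccore", id=",".join(accessions), rettype="gb", retmode="text"
    )
    out = {}
    for record in SeqIO.parse(handle, "genbank"):
        for feature in record.features:
            if feature.type != "CDS":
                continue
            cds = str(feature.extract(record.seq))
            organism = record.annotations.get("organism", record.id)
            label = organism.replace(" ", "_")
            out[f"{label}|{record.id}"] = cds.upper()
            break
    return out


def protein_guided_alignment(seqs: dict[str, str]) -> dict[str, str]:
    """Align translated proteins with mafft; thread codons back."""
    from Bio.Seq import Seq

    proteins = {
        name: str(Seq(s[: len(s) - len(s) % 3]).translate().rstrip("*"))
        for name, s in seqs.items()
    }
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        for name, aa in proteins.items():
            fh.write(f">{name}\n{aa}\n")
        tmp = fh.name
    aligned = subprocess.run(
        ["mafft", "--auto", tmp], capture_output=True, text=True, check=True
    ).stdout
    out = {}
    for record in SeqIO.parse(StringIO(aligned), "fasta"):
        nt = seqs[record.id]
        threaded, k = [], 0
        for aa in str(record.seq):
            if aa == "-":
                threaded.append("---")
            else:
                threaded.append(nt[3 * k : 3 * k + 3])
                k += 1
        out[record.id] = "".join(threaded)
    return out


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="NCBI Entrez contact email")
    parser.add_argument("--out", default="data/real", type=Path)
    args = parser.parse_args()
    Entrez.email = args.email

    args.out.mkdir(parents=True, exist_ok=True)
    seqs = fetch_cds(STUDY_ACCESSIONS + REFERENCE_ACCESSIONS)
    avp = {n: s for n, s in seqs.items() if len(s) <= 600}
    avpr1a = {n: s for n, s in seqs.items() if len(s) > 600}
    for gene, subset in (("avp", avp), ("avpr1a", avpr1a)):
        aligned = protein_guided_alignment(subset)
        path = args.out / f"{gene}_aligned.fasta"
        with open(path, "w") as fh:
            for name, s in aligned.items():
                fh.write(f">{name}\n{s}\n")
        print(f"wrote {len(aligned)} sequences to {path}")
    meta = args.out / "metadata.tsv"
    if not meta.exists():
        with open(meta, "w") as fh:
            fh.write("taxon\tgenus\tfamily\tgroup\tmonogamy\n")
        print(f"wrote metadata template to {meta} (fill in before analysis)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
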