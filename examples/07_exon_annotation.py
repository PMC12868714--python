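"""Exon frame and skipping-isoform annotation from a GTF.

For a targeted cassette exon: find transcripts that include or skip it,
decide whether skipping preserves the reading frame (coding overlap
divisible by 3), pick strict skipping isoforms (coding sequence identical
except for the exon), and the longest skipping mRNA.
"""

import tempfile
from pathlib import Path

from hgscreen.annotation import (TargetedExon, annotate_exons,
                                 load_annotation)


def write_demo_gtf(path: Path) -> None:
    def line(feat, s, e, tx=None):
        attrs = 'gene_id "GENE1";'
        if tx:
            attrs += f' transcript_id "{tx}";'
        return f"chr1\tdemo\t{feat}\t{s}\t{e}\t.\t+\t.\t{attrs}"

    rows = [line("gene", 101, 800)]
    transcripts = {
        # includes the 198-nt cassette exon at 301-498
        "TX_INC": ([(101, 200), (301, 498), (601, 700)],
                   [(151, 200), (301, 498), (601, 650)]),
        # skips it with otherwise identical coding sequence
        "TX_SKIP": ([(101, 200), (601, 700)], [(151, 200), (601, 650)]),
        # skips it but extends the terminal exon (different stop)
        "TX_LONG": ([(101, 200), (601, 790)], [(151, 200), (601, 655)]),
    }
    for tx, (exons, cds) in transcripts.items():
        rows.append(line("transcript", exons[0][0], exons[-1][1], tx))
        rows.extend(line("exon", s, e, tx) for s, e in exons)
        rows.extend(line("CDS", s, e, tx) for s, e in cds)
    path.write_text("\n".join(rows) + "\n")


with tempfile.TemporaryDirectory() as td:
    gtf = Path(td) / "demo.gtf"
    write_demo_gtf(gtf)
    db = load_annotation(gtf)
    exon = TargetedExon(chrom="chr1", start=301, end=498, strand="+",
                        gene_id="GENE1")
    table = annotate_exons(db, [exon])

row = table.iloc[0]
print(f"targeted exon {row['chrom']}:{row['start']}-{row['end']} "
      f"({row['exon_length']} nt)")
print(f"frame preserving: {row['frame_preserving']} "
      f"(deletes {row['deleted_coding_length']} coding nt = "
      f"{row['deleted_coding_length'] // 3} amino acids)")
print(f"inclusion isoforms:      {row['inclusion_transcripts']}")
print(f"skipping isoforms:       {row['skipping_transcripts']}")
print(f"strict skipping:         {row['strict_skipping_transcripts']}")
print(f"longest skipping:        {row['longest_skipping_transcript']}")
# 198 nt is divisible by 3, so skipping removes exactly 66 residues from
# the protein; TX_SKIP is 'strict' (coding change limited to the exon)
# while TX_LONG wins 'longest' despite its different 3' end.
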