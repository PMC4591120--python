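"""Assembly QC: N50, AT content and Ortholog Hit Ratio on a toy assembly.

Builds a small set of transcript-like sequences, computes the standard
length statistics, then scores completeness against a mock best-hit table.
"""

import numpy as np

from ksdater import SeqRecord, HitRecord, length_stats, coverage_depth
from ksdater.assembly_qc import best_hits, ortholog_hit_ratio

rng = np.random.default_rng(0)
transcripts = [
    SeqRecord(id=f"unigene{i}", seq="".join(rng.choice(list("ACGT"),
                                                       size=int(L))))
    for i, L in enumerate(rng.gamma(shape=2.0, scale=400, size=300) + 200)
]

stats = length_stats(transcripts)
print(f"{stats.n_seqs} transcripts, {stats.total_bases:,} bases")
print(f"mean length {stats.mean_len:.0f} bp, N50 {stats.n50} bp, "
      f"AT content {stats.at_content:.1%}")
# N50: transcripts of at least this length hold half the assembled bases.

depth = coverage_depth(cleaned_read_bases=50 * stats.total_bases,
                       unigene_bases=stats.total_bases)
print(f"coverage depth at 50x read bases: {depth:.1f}x")

# Ortholog Hit Ratio: query bases covered by the best protein hit divided
# by 3x the matched protein length; OHR >= 1 means a full-length transcript.
hits = []
for t in transcripts[:100]:
    covered = int(len(t.seq) * rng.uniform(0.3, 1.0))
    hits.append(HitRecord(t.id, "proteinA", 80.0, covered, 0, 0,
                          1, covered, 1, covered // 3, 1e-30, 100.0))
records, summary = ortholog_hit_ratio(best_hits(hits), {"proteinA": 150})
print(f"\nOHR over {summary.n_queries} queries: "
      f"{summary.n_full_length} full-length (OHR >= 1), "
      f"{summary.n_over_75} above 0.75, {summary.n_over_50} above 0.5")
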