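"""End to end: synthesize training data, learn a profile, simulate reads.

A toy genome and mapped reads with planted adapters, qualities and
systematic errors are generated; a profile is trained from the SAM and then
used to simulate a fresh FASTQ pair with a truth sidecar.
"""

import collections
import tempfile
from pathlib import Path

from readsmith.fixtures import TruthProfile, make_genome, make_mapped_reads
from readsmith.sim import simulate
from readsmith.train import TrainingReport, train_profile

workdir = Path(tempfile.mkdtemp(prefix="readsmith_"))
genome = make_genome(seed=11, lengths=[20_000], gc=0.5)
truth = TruthProfile.smooth(
    12, sys_density=5e-4, frag_sd=40,
    adapter1="AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC",
    adapter2="AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA",
)
make_mapped_reads(genome, truth, 15_000, seed=1, sam_path=workdir / "toy.sam")

report = TrainingReport()
profile = train_profile(workdir / "toy.sam", genome, min_fit_sites=3_000,
                        max_fits=3, report=report)
print(f"trained on {report.n_pairs} pairs; "
      f"{report.n_systematic} systematic errors called; "
      f"{report.n_converged}/{report.n_fits} bias fits converged")
print(f"inferred adapter (read 1): {profile.adapter_set.first[0]}")
print(f"dispersion alpha={profile.combined.dispersion.alpha:.3g} "
      f"beta={profile.combined.dispersion.beta:.3g}")

result = simulate(genome, profile, str(workdir / "sim"), seed=2,
                  n_pairs=5_000)
lengths = collections.Counter()
with open(result.truth_path) as fh:
    next(fh)
    for line in fh:
        f = line.split("\t")
        lengths[int(f[2]) - int(f[1])] += 1
mean_len = sum(l * c for l, c in lengths.items()) / result.n_pairs
print(f"simulated {result.n_pairs} pairs -> {result.fastq1}")
print(f"mean simulated fragment length: {mean_len:.1f} "
      f"(training mean {truth.frag_mean})")
# the simulated fragment-length mean tracks the training data because the
# length bias is learned from the corrected pair counts
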