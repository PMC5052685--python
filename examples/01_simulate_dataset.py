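"""Generate a synthetic crosslinking study and inspect its ground truth.

A fraction of transcripts carry tandem CUUC-N5-CACC elements planted in
their CDS; two read replicates concentrate T-to-C conversions there.
"""

import parclipkit as pk

cfg = pk.SimulationConfig(seed=42, n_transcripts=200)
transcripts, truth = pk.generate_transcriptome(cfg)
reads1 = pk.simulate_parclip_replicate(transcripts, truth, cfg, replicate=1)
reads2 = pk.simulate_parclip_replicate(transcripts, truth, cfg, replicate=2)

n_sites = sum(len(v) for v in truth.planted_sites.values())
conv1 = sum(1 for r in reads1 if r.tc_positions)
print(f"transcripts: {len(transcripts)}  targets: {len(truth.target_ids)}")
print(f"planted tandem sites: {n_sites} (= targets x {cfg.tandems_per_target})")
print(f"replicate 1: {len(reads1)} reads, {conv1} carry a T-to-C conversion")
print(f"replicate 2: {len(reads2)} reads")
print()
print("Conversion-carrying reads are the crosslink evidence every later")
print("stage consumes; the planted intervals are the recovery truth.")
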