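"""Sliding-window nucleotide diversity and hyper-variable region screening.

Simulates a full-length 32-accession plastome matrix, removes one inverted
repeat (so the duplicated region is counted once), scans Pi in 1000 bp
windows every 300 bp and extracts regions with Pi > 0.003 — the candidate
taxon-specific barcodes.
"""

import barcodescreen as bs

dataset = bs.simulate_dataset(bs.SimulationConfig(seed=4))
structure = bs.analyze_structure(dataset.alignment.to_records()[0])
core = bs.remove_one_ir(dataset.alignment, structure)

count, pct = bs.count_polymorphic_sites(core)
print(f"matrix: {core.n_sequences} accessions x {core.length} columns")
print(f"polymorphic sites: {count} ({pct}%)")

profile = bs.sliding_window_pi(core, window=1000, step=300)
print(f"Pi range: 0 to {profile.max_pi():.4f} over {len(profile.windows)} windows")

regions = bs.extract_hypervariable_regions(profile, threshold=0.003)
loci = {l.name: l for l in dataset.loci}
print(f"hyper-variable regions (Pi > 0.003): {len(regions)}")
for start, end, peak in regions[:5]:
    inside = [
        l.name for l in dataset.loci
        if l.multiplier > 1 and start < l.end and end > l.start
    ]
    print(f"  [{start:>6}, {end:>6})  peak Pi {peak:.4f}  elevated loci: {inside}")

# Peaks coincide with the loci the generator evolved at an elevated mutation
# rate; on real data these would be nominated for barcode primer design.
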