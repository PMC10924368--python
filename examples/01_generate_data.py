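"""Generate labeled BPSD datasets from the regularity tables.

Each sample is a vector of discrete factor levels drawn uniformly from
the admissible range of its (BPSD type, severity) table cell; severity
"none" produces the no-BPSD label regardless of the generating type.
"""

from bpsdmon import generate_dataset, load_table, lookup_range

table = load_table("bephyen")

rng = lookup_range(table, "hrv", 2, "high")  # depression, high severity
print(f"HRV range under high depression: {rng.lo}-{rng.hi} "
      "(low heart-rate variability accompanies depression)")

ds = generate_dataset(table, seed=0)
print(f"\nGenerated {len(ds)} samples; label counts {ds.label_counts()}")
print("(0=agitation, 1=apathy, 2=depression, 3=no BPSD)\n")
print(ds.to_frame().head(8).to_string(index=False))
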