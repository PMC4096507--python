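# Reference data layout

The acceptance tests for the published season statistics expect the field
study's deposited matrices here, converted to plain CSV:

```
data/
  dataset_s1/
    2008.csv          # individuals x prey taxa counts, first row = taxon
    2009.csv          # labels, first column = individual labels
    2010.csv
  table_s1_availability_2008.csv   # taxon, availability count (one season
  table_s1_availability_2010.csv   # per file; first column = taxon label)
```

These files are not redistributed with the package; without them the
corresponding tests report the values as unavailable. All other tests and
the acceptance script are self-contained (synthetic data only).
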