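# File formats

## Unicorn-style paired-column export (`.txt` / `.csv`)

Every series (curve or event list) owns an adjacent pair of columns:
volume, then value. Row 1 carries the series name over the first column of
its pair; row 2 carries the units. Series may have different lengths —
shorter columns simply end in empty cells.

```
UV 1_280		UV 2_260		Fraction
ml	mAU	ml	mAU	ml	(Fractions)
0.0	2.1	0.0	1.3	8.0	1
0.002	2.0	0.002	1.2	8.5	2
0.004	2.2			9.0	3
```

Column pairs are classified by the unit row: `(Fractions)` → fraction
marks, `Injection` → injection events, `Logbook` → log entries, numeric →
a curve. Supported dialects: UTF-8 / UTF-16-LE / UTF-16-BE / latin-1
encodings, tab / semicolon / comma delimiters, `.` or `,` decimal mark
(delimiter and decimal mark must differ). `detect_dialect` infers all
three from the raw bytes; pass a `DialectDescriptor` to override, e.g. for
a header convention from another software version.

## Generic template (non-Äkta instruments)

Tab-separated, UTF-8. Row 1 names, row 2 units. Column 1 is the volume
axis shared by all curves; each further numeric column is one curve
(shorter curves end with empty trailing cells); an optional trailing
(volume, label) pair holds fraction starts:

```
Volume	UV 280	UV 260	Fraction start	Fraction
ml	mAU	mAU	ml	(Fractions)
0.0	0.0	0.0	0.0	1
1.0	0.0	0.0	1.0	2
2.0	0.0	0.0
```

A blank copy ships as `examples/template_example.txt` and is emitted by
`chromaplot template`. Fill in your instrument's numbers, save as `.txt`,
and every chromaplot feature works on it.
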