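sample_id	phenotype	breed	yield_gb	mapped_pct	ibd_mapped_pct	mean_coverage
Horse1	case	American Miniature	2.4	95.4	93.1	10901.8
Horse2	case	Icelandic Horse	2.8	94.8	91.1	12624.0
Horse3	case	Icelandic Horse	2.8	97.8	96.0	13385.2
Horse4	case	Rocky Mountain Horse	3.0	96.6	94.5	13522.2
Horse5	case	Rocky Mountain Horse	2.4	94.6	92.4	11187.2
Horse6	intermediate	American Miniature	2.8	94.1	90.7	12615.1
Horse7	control	American Miniature	2.6	97.0	95.1	11493.6
Horse8	control	American Miniature	2.4	94.9	92.4	11104.2
Horse9	control	Rocky Mountain Horse	2.4	92.4	90.8	10489.8
Horse10	control	Rocky Mountain Horse	12.4	97.9	96.5	57357.6
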