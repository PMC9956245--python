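strain	AcoPra	AgTrS	AgUmASt1	AgUmASH1	ACN14a	AvcI1	CpI1-S	ACN1ag	AvVan	AiOr	ARgP5	QA3
AcoPra	100.00	98.82	98.82	98.82	79.01	78.40	79.32	79.63	79.32	79.94	77.23	80.56
AgTrS	98.82	100.00	100.00	100.00	79.17	78.57	79.46	79.76	79.46	80.06	77.15	80.36
AgUmASt1	98.82	100.00	100.00	100.00	79.17	78.57	79.46	79.76	79.46	80.06	77.15	80.36
AgUmASH1	98.82	100.00	100.00	100.00	79.17	78.57	79.46	79.76	79.46	80.06	77.15	80.36
ACN14a	79.01	79.17	79.17	79.17	100.00	99.43	93.16	93.45	90.88	90.88	80.12	91.45
AvcI1	78.40	78.57	78.57	78.57	99.43	100.00	92.59	92.88	90.31	90.31	79.54	90.88
CpI1-S	79.32	79.46	79.46	79.46	93.16	92.59	100.00	99.72	90.03	90.03	79.83	90.88
ACN1ag	79.63	79.76	79.76	79.76	93.45	92.88	99.72	100.00	90.31	90.31	80.12	91.17
AvVan	79.32	79.46	79.46	79.46	90.88	90.31	90.03	90.31	100.00	98.86	78.10	93.45
AiOr	79.94	80.06	80.06	80.06	90.88	90.31	90.03	90.31	98.86	100.00	78.10	93.45
ARgP5	77.23	77.15	77.15	77.15	80.12	79.54	79.83	80.12	78.10	78.10	100.00	80.98
QA3	80.56	80.36	80.36	80.36	91.45	90.88	90.88	91.17	93.45	93.45	80.98	100.00
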