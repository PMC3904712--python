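>TaHsfA2b_synthetic_standin synthetic stand-in; composition solved to match the published TaHsfA2b summary statistics (413 aa, 45.6 kDa, pI 4.99); not the real sequence
MHWIGEDLGLGQMGCKRNFLTYVDNRLARPERASSYSLLYFVRILDDVNYQRFRVHVFQI
EAAHLLPYNRTVAQREVRVLGLSQQLWTSSGQTTDLHTGTFALVTDLLNGIRVLPAVPSI
QISSNVAYYSSQQQEPRQEAPSSVFFKGQIASADPDEQLQAGNCDIIAIVVGAPKVGVLG
ASQVLICNFGHQQLHSQYTQEINLGRSRDGGLKLTWQLTDLDVPYGAMTVRTLDPLVEMI
ALQWFFFAQLQLQVIIKGEAQASHKTNARTADRDLMAQEEIENRSATICTVAITKYTAGA
GPSIADSMNYEGEPDDHMSHDIQESMYGNVDNWNSEGIVENAETQRIAREAQFPNPFISA
ETCFKIRVQPRMAKAPCQGFAPLEGAFPASGRADGQVATAMQSPELVAQGADQ
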