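0.000298231637167
0.0452051024074 0.0166361220574
0.000107538117828 0.00258382587713 0.000289426124263
0.00216830313559 0.000966510216573 0.00052426534679 0.00181202449212
0.00509264985532 0.000579271376439 0.000235361554289 0.0021233852555 6.49474644367e-05
0.002172126147 0.00510094579187 0.000541025710113 0.0029404296601 0.000761097883121 0.00394156540585
0.00681859728895 0.000738424118104 0.00102769943095 0.00202603903856 0.000381945595338 0.000463037973116 0.0145151519773
0.0036145917284 0.00026879649952 2.5151822287e-05 0.000539419183279 0.00250469831233 0.0023498402127 0.00188191837566 0.00175071037429
0.000430611760661 0.000593131482136 0.000921078905681 0.018915160455 0.00165878278514 0.0130392458825 0.00035545424998 0.000154351621143 0.000886536911518
0.000236490142777 0.000350484843881 0.00622185813418 0.00237369056485 5.78502393122e-05 0.00125332443342 0.00461945775564 0.00861756314771 0.00476688514308 0.000264120067196
0.010126077974 0.00102981591316 0.000922527435872 9.38189903302e-05 0.00048818926745 0.0493501023916 0.00121710625839 0.0108066864179 0.000647241774343 0.0056075423995 0.0132041468669
0.104125787758 0.00561122224861 0.122134088166 9.02891198659e-05 0.00243227791327 0.000896503597306 0.00344804504929 0.00351748008692 0.00262497414614 0.000638570269603 0.0218721259764 0.00175418974152
0.00107347739202 0.0013628827324 0.00181787208008 0.00109626101582 0.000486222467665 0.000373239227446 0.000430798697279 0.00212865633836 0.00539450803778 0.0100110844247 0.00105621787726 0.00121408443796 0.00384261787839
0.00275150835507 0.00227257819729 0.00974768199471 0.00616396348684 0.00040494662425 0.000243934301363 0.030302281965 0.00194010833923 0.000204677944325 0.00454020673872 3.46878575131e-05 0.000109351232234 0.00426584665267 0.0862464751873
0.000857947238621 0.00057308251964 0.00349544347215 0.000299465844251 0.0012365213913 0.00109110501634 0.000167995142518 0.00225078458714 0.00271195220692 0.000535594883385 0.00118836851566 9.3880728305e-06 0.000340440928864 0.000308548553843 0.00656170682955
0.000625177529013 0.00101142938713 0.0122957855615 5.70468342474e-05 0.00481069862188 0.000100984709768 4.59991144914e-05 0.000721246257606 0.0105092773523 0.000201626421347 0.00339408631581 0.00113593883008 0.000433022656187 0.000586511004137 0.000202947525591 0.0029229532692
0.000266437710416 0.00151008305698 0.00240618296494 0.00307430544995 0.00043002766302 8.25049958053e-05 0.00560062377067 0.000336237063835 0.00282675585963 0.0018890858421 0.0178958513927 0.000614249984088 0.000654625403004 0.037732510945 0.000687311787642 0.00362275731921 0.00145478176614
0.00697142343547 0.00516241290936 0.00230459934231 0.00287487243576 0.000143009183673 0.000414174855069 0.000334950865047 3.90030926744e-05 0.00125018804175 0.000744311490786 0.000617565636266 0.000530562524125 0.00221274182362 0.00459687474258 0.0477222167638 0.00152094128867 0.0100526094786 0.000206930904593
0.000784086871556 0.000306291247441 0.000158205282743 9.66221577513e-05 0.00018682587176 0.000127090481696 3.88754008475e-05 0.00355853172779 0.00149568630704 0.00552123743067 0.000500263144282 0.00159910332126 0.0102883384495 5.37468634461e-05 0.000329138019552 0.00101466249677 0.00147692133638 0.00176071364185 0.000315624346056

0.0454098669919 0.0669886175255 0.051243099239 0.0403320007391 0.0467439475779 0.0523678774683 0.047903343422 0.0448576441437 0.0467271547826 0.0601931729825 0.0595063420254 0.0438501204319 0.0526399350201 0.0640480633163 0.0442451088284 0.0666361331182 0.0318502149277 0.0485645574572 0.049880631067 0.0360121689355
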