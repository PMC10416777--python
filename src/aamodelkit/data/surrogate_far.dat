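0.00525239317298
0.00453808908019 0.0056844328347
0.00761964242332 0.00688499986281 0.00297025030797
0.00198983406625 0.00723521203383 0.00268875374689 0.0139636676869
0.00353469325823 0.00577383218259 0.00402169763252 0.0028517739374 0.00577124291558
0.00240409747472 0.00440652780767 0.00213097770071 0.0076594153272 0.004430005161 0.00201021181211
0.00215815702928 0.00763464804214 0.00227512254798 0.00240874768904 0.0102583238958 0.00193282842599 0.00891986321801
0.0068470405241 0.00360826324774 0.0145329184143 0.00665032098525 0.00868063718884 0.00281496754046 0.0018544109648 0.00650421637021
0.00307533446664 0.00497805759232 0.00314542503391 0.00466717087342 0.00280879565896 0.00978882100881 0.00316242303047 0.00385239911992 0.0144331645941
0.00233751160921 0.00247091305538 0.00649850388289 0.00419725409465 0.00823509117555 0.00346739011463 0.00646153943532 0.00772324597111 0.00420005552343 0.00405989418455
0.00349669927164 0.00329163346543 0.00252294271244 0.00357872904839 0.00230161596024 0.00683847350217 0.00244688230981 0.00258076364515 0.00611195093081 0.00308877157311 0.00555360797795
0.00764452490685 0.00438685446046 0.00598154501736 0.009921720871 0.0143968203599 0.00486659553675 0.00325834845736 0.00303437417805 0.00559562653154 0.00266994405583 0.00333381709875 0.00230731384683
0.0128553595768 0.00773845524721 0.00146357510714 0.00211596070961 0.00424205444632 0.0127968627013 0.00531317250892 0.00516800534985 0.00355895633784 0.00242503640472 0.00380504061298 0.00273951467857 0.0124057382919
0.00391987389756 0.00454902440227 0.00287678682021 0.0014584964869 0.00609681109563 0.00433026800435 0.00321212909272 0.00289316542864 0.00950195583454 0.00411666460306 0.00509173290985 0.00236774895727 0.00469363879811 0.00302036415366
0.0061414683013 0.00805828522005 0.00150860815322 0.00547911807752 0.0043420222133 0.00631345087925 0.00458344796612 0.00822693633074 0.00288497820069 0.00431814329221 0.00459567517065 0.00969801499146 0.00342692526541 0.0047885698188 0.00241137789032
0.00497991856723 0.0054437137827 0.00736327663981 0.00433414464337 0.00477066663524 0.00257382741442 0.00451695085635 0.00678364221394 0.00178006232334 0.0062893118231 0.00831846650179 0.00632497049319 0.00936136418171 0.0101836000991 0.00479469236159 0.00148266237888
0.00391471201659 0.00574977911724 0.00873766502717 0.00305203335384 0.00699817545474 0.00582032982187 0.00184315812875 0.00767126385173 0.002219590679 0.0115247348156 0.00988607859296 0.00317001394874 0.00577584288581 0.00279662895066 0.00397282900501 0.00396728596885 0.0136733820535
0.00577567473862 0.00659319147189 0.00590244564166 0.00333362569792 0.00718966878108 0.00729283622119 0.00807907707937 0.0074305138548 0.00403544607999 0.008629832529 0.00542701288553 0.00672054216848 0.00516211697252 0.00453966617318 0.00893501910934 0.00399336891267 0.00481881269016 0.00200043551159
0.00195711772097 0.00263997095405 0.0054025797276 0.00395273895702 0.00431005074927 0.0112589408635 0.00557727844019 0.00275603841482 0.00121080100141 0.00520932887251 0.00170415935898 0.00682549208233 0.00379620442346 0.010950312469 0.00523736757054 0.00470778462616 0.00601743882182 0.00476499300336 0.00457916395458

0.0393918176537 0.0514482148678 0.0466732565607 0.0508008475034 0.041486236994 0.0381241109293 0.0366871080254 0.0626990496196 0.0584709926832 0.058679683327 0.0414859203537 0.043462906832 0.051880979495 0.0545974263232 0.063045040922 0.0459302459867 0.052169279619 0.0424681763018 0.067072578764 0.0534261272385
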