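((((((((t1:0.202229466306,t6:0.455695115543):0.154878238959,t24:0.0341185380932):0.453898615233,t25:0.00062633250889):0.0449533277644,(t13:0.052643760963,t18:0.130055155735):0.405087520088):0.168024175065,((t5:0.0535000668341,t11:0.146102143032):0.384404528608,t9:0.119252986088):0.176836199166):0.137521082277,(t19:0.239320803664,t26:0.0899208989307):0.442129741071):0.221653631229,t7:0.129851436348):0.0698127791118,(t2:0.0660194943553,t10:0.0588655538076):0.279914405535,((t3:0.0246317173763,(t4:0.0408881090194,(((((t8:0.189400619969,t23:0.0709523493261):0.228554101039,t12:0.0861184555117):0.137555427901,t16:0.0169328464907):0.0302181673488,(t15:0.348336218108,(t17:0.0473796537691,t20:0.0602357722329):0.083424387661):0.0198606232007):0.0236994053673,(t14:0.393048258485,t21:0.115597661586):0.205653386997):0.275925491606):0.00820009544689):0.0809538772387,t22:0.339439882891):0.195677495115);
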